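"""Reading and writing case/response tables (CSV or JSON).

The table dialect: a cases table with columns (case_id, correct_text,
[specialty], [chief_complaint]) and a responses table with columns
(case_id, user_id, rank, diagnosis_text, [tenure]).  The JSON equivalent
is a list of case objects with an embedded ``responses`` list.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .records import CaseRecord, Response

__all__ = [
    "read_case_tables",
    "read_cases_json",
    "write_case_tables",
    "write_mapped_tables",
]


def _opt(row, name: str) -> str | None:
    val = row.get(name)
    if val is None or (isinstance(val, float) and pd.isna(val)) or val == "":
        return None
    return str(val)


def read_case_tables(cases_path: str | Path, responses_path: str | Path) -> list[CaseRecord]:
    """Load cases + responses CSVs into CaseRecords."""
    cases_df = pd.read_csv(cases_path, dtype=str)
    resp_df = pd.read_csv(responses_path, dtype={"rank": int}).astype({"case_id": str})
    by_case: dict[str, list[Response]] = {}
    for row in resp_df.to_dict("records"):
        by_case.setdefault(str(row["case_id"]), []).append(
            Response(
                user_id=str(row["user_id"]),
                rank=int(row["rank"]),
                text=str(row["diagnosis_text"]),
                tenure=_opt(row, "tenure"),
            )
        )
    records = []
    for row in cases_df.to_dict("records"):
        cid = str(row["case_id"])
        records.append(
            CaseRecord(
                case_id=cid,
                correct_text=str(row["correct_text"]),
                responses=by_case.get(cid, []),
                specialty=_opt(row, "specialty"),
                chief_complaint=_opt(row, "chief_complaint"),
            )
        )
    return records


def read_cases_json(path: str | Path) -> list[CaseRecord]:
    """Load the JSON case dialect (list of case objects with responses)."""
    data = json.loads(Path(path).read_text())
    records = []
    for c in data:
        records.append(
            CaseRecord(
                case_id=str(c["case_id"]),
                correct_text=c["correct_text"],
                specialty=c.get("specialty"),
                chief_complaint=c.get("chief_complaint"),
                responses=[
                    Response(
                        user_id=str(r["user_id"]),
                        rank=int(r["rank"]),
                        text=r["diagnosis_text"],
                        tenure=r.get("tenure"),
                    )
                    for r in c.get("responses", [])
                ],
            )
        )
    return records


def write_case_tables(
    cases: Sequence[CaseRecord],
    cases_path: str | Path,
    responses_path: str | Path,
) -> None:
    cases_df, resp_df = case_frames(cases, mapped=False)
    cases_df.to_csv(cases_path, index=False)
    resp_df.to_csv(responses_path, index=False)


def case_frames(
    cases: Iterable[CaseRecord], mapped: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy DataFrames for cases and responses; mapping columns optional."""
    case_rows, resp_rows = [], []
    for c in cases:
        row = {
            "case_id": c.case_id,
            "correct_text": c.correct_text,
            "specialty": c.specialty,
            "chief_complaint": c.chief_complaint,
        }
        if mapped:
            row.update(
                status=c.correct_status,
                concept_id=c.correct_concept_id,
                excluded=c.excluded,
                empty=c.empty,
            )
        case_rows.append(row)
        for r in c.responses:
            rrow = {
                "case_id": c.case_id,
                "user_id": r.user_id,
                "rank": r.rank,
                "diagnosis_text": r.text,
                "tenure": r.tenure,
            }
            if mapped:
                rrow.update(status=r.status, concept_id=r.concept_id,
                            similarity=r.similarity)
            resp_rows.append(rrow)
    return pd.DataFrame(case_rows), pd.DataFrame(resp_rows)


def write_mapped_tables(
    cases: Sequence[CaseRecord],
    cases_path: str | Path,
    responses_path: str | Path,
) -> None:
    """Write the input tables with appended (status, concept_id, similarity)."""
    cases_df, resp_df = case_frames(cases, mapped=True)
    cases_df.to_csv(cases_path, index=False)
    resp_df.to_csv(responses_path, index=False)
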