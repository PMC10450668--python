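"""Case/response records: one case's correct diagnosis plus each user's
ranked free-text differential, before and after concept mapping."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = ["Response", "CaseRecord"]


@dataclass
class Response:
    """One diagnosis entry of one user's differential for one case."""

    user_id: str
    rank: int  # 1-based position in the user's ranked list
    text: str
    tenure: str | None = None
    # filled in by mapping
    status: str | None = None  # matched | ambiguous_resolved | unmatched
    concept_id: str | None = None
    similarity: float | None = None

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError(f"rank must be >= 1, got {self.rank}")


@dataclass
class CaseRecord:
    """A case: its correct-diagnosis text and the users' ranked differentials."""

    case_id: str
    correct_text: str
    responses: list[Response] = field(default_factory=list)
    specialty: str | None = None
    chief_complaint: str | None = None
    # filled in by mapping
    correct_concept_id: str | None = None
    correct_status: str | None = None
    excluded: bool = False  # correct diagnosis could not be mapped
    empty: bool = False  # no user diagnosis survived mapping

    @property
    def user_ids(self) -> list[str]:
        return sorted({r.user_id for r in self.responses})

    def copy(self) -> "CaseRecord":
        return replace(self, responses=[replace(r) for r in self.responses])
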