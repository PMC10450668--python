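"""Group-enumeration simulation of collective diagnostic accuracy.

For every case, every group size k, and every scoring rule, all C(n, k)
unique k-member groups are formed (or a seeded sample of them), each
group's differentials are aggregated into a collective ranking, and the
ranking is tested for whether an accepted concept appears in the top 1, 2
or 3 positions.  The accepted set is the correct concept alone (exact
matching) or optionally widened to its direct parent and/or child
concepts (hierarchy credit).  Per-case accuracy is the fraction of groups
that hit; the reported accuracy is the unweighted mean over cases, so
every case counts equally regardless of how many groups it contributes.

Strata: case-level labels (specialty, chief complaint) filter the case
set; tenure restricts each case's user pool to one tenure level before
enumeration, keeping the comparison within cases.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
import random
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .aggregate import (
    DiagnosisEntry,
    RULE_ALIASES,
    RULES,
    aggregate,
    entries_from_case,
    top_k_contains,
)
from .mapping import DEFAULT_PRIORITY, TagPriority
from .ontology import OntologyGraph
from .records import CaseRecord

__all__ = [
    "MATCH_MODES",
    "SimulationConfig",
    "enumerate_groups",
    "accepted_set",
    "simulate",
]

logger = logging.getLogger(__name__)

EXACT = "exact"
PLUS_PARENTS = "exact+parents"
PLUS_CHILDREN = "exact+children"
PLUS_BOTH = "exact+both"
MATCH_MODES = (EXACT, PLUS_PARENTS, PLUS_CHILDREN, PLUS_BOTH)


@dataclass(frozen=True)
class SimulationConfig:
    """What to sweep: group sizes, rules, top-k cutoffs, match modes, strata."""

    group_sizes: tuple[int, ...] = tuple(range(1, 11))
    rules: tuple[str, ...] = RULES
    top_k: tuple[int, ...] = (1, 2, 3)
    match_modes: tuple[str, ...] = (EXACT,)
    seed: int = 0
    sample_groups: int | None = None  # None = exhaustive enumeration
    stratify_by: str | None = None  # None | specialty | chief_complaint | tenure
    min_per_tenure: int = 3
    tenure_levels: tuple[str, ...] = ("medical student", "resident", "attending physician")
    priority: TagPriority = DEFAULT_PRIORITY

    def __post_init__(self) -> None:
        for rule in self.rules:
            if RULE_ALIASES.get(rule, rule) not in RULES:
                raise ValueError(f"unknown rule {rule!r}")
        for mode in self.match_modes:
            if mode not in MATCH_MODES:
                raise ValueError(f"unknown match mode {mode!r}")
        if any(k < 1 for k in self.group_sizes) or any(k < 1 for k in self.top_k):
            raise ValueError("group sizes and top-k cutoffs must be >= 1")
        if self.sample_groups is not None and self.sample_groups < 1:
            raise ValueError("sample_groups must be >= 1 when sampling")


def enumerate_groups(user_ids: Sequence[str], k: int) -> list[tuple[str, ...]]:
    """All unique k-subsets of ``user_ids``, in canonical sorted order."""
    if k > len(user_ids):
        raise ValueError(f"group size {k} exceeds {len(user_ids)} users")
    return list(itertools.combinations(sorted(user_ids), k))


def sample_groups(
    user_ids: Sequence[str], k: int, n_samples: int, rng: random.Random
) -> list[tuple[str, ...]]:
    """Seeded sample of distinct k-subsets (all of them if fewer exist)."""
    all_groups = enumerate_groups(user_ids, k)
    if n_samples >= len(all_groups):
        return all_groups
    return rng.sample(all_groups, n_samples)


def accepted_set(correct_id: str, graph: OntologyGraph, match_mode: str) -> set[str]:
    """Concepts counted as correct under a hierarchy-credit mode."""
    if correct_id not in graph:
        raise KeyError(correct_id)
    accepted = {correct_id}
    if match_mode in (PLUS_PARENTS, PLUS_BOTH):
        accepted |= graph.parents(correct_id)
    if match_mode in (PLUS_CHILDREN, PLUS_BOTH):
        accepted |= graph.children(correct_id)
    if match_mode not in MATCH_MODES:
        raise ValueError(f"unknown match mode {match_mode!r}")
    return accepted


def _group_seed(global_seed: int, case_id: str, k: int, group_idx: int, rule: str) -> int:
    digest = hashlib.blake2b(
        f"{global_seed}|{case_id}|{k}|{group_idx}|{rule}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)


def _eligible(cases: Iterable[CaseRecord]) -> list[CaseRecord]:
    kept = []
    for case in cases:
        if case.excluded:
            continue
        if case.empty:
            logger.warning("case %s has no surviving diagnoses; skipped", case.case_id)
            continue
        kept.append(case)
    return kept


def _simulate_stratum(
    cases: list[CaseRecord],
    graph: OntologyGraph,
    config: SimulationConfig,
    stratum: str | None,
    user_filter: str | None = None,
) -> list[dict]:
    """Accuracy cells for one stratum (or the unstratified whole)."""
    rules = tuple(RULE_ALIASES.get(r, r) for r in config.rules)
    max_top = max(config.top_k)
    rng = random.Random(config.seed)
    cells: dict[tuple, list[float]] = defaultdict(list)
    groups_per_case: dict[int, list[int]] = defaultdict(list)

    for case in cases:
        entries = entries_from_case(case)
        if user_filter is not None:
            tenure_of = {r.user_id: r.tenure for r in case.responses}
            entries = [e for e in entries if tenure_of.get(e.user_id) == user_filter]
        by_user: dict[str, list[DiagnosisEntry]] = defaultdict(list)
        for e in entries:
            by_user[e.user_id].append(e)
        users = sorted(by_user)
        if not users:
            continue
        tags = {
            e.concept_id: graph.semantic_tag(e.concept_id)
            for e in entries
            if e.concept_id in graph
        }
        accepted = {
            mode: accepted_set(case.correct_concept_id, graph, mode)
            for mode in config.match_modes
        }
        for k in config.group_sizes:
            if k > len(users):
                continue
            if config.sample_groups is None:
                groups = enumerate_groups(users, k)
            else:
                groups = sample_groups(users, k, config.sample_groups, rng)
            groups_per_case[k].append(len(groups))
            hits: dict[tuple, int] = defaultdict(int)
            for gi, group in enumerate(groups):
                group_entries = [e for u in group for e in by_user[u]]
                for rule in rules:
                    ranking = aggregate(
                        group_entries,
                        rule,
                        priority=config.priority,
                        tie_seed=_group_seed(config.seed, case.case_id, k, gi, rule),
                        tags=tags,
                    )
                    top_ids = ranking.concept_ids[:max_top]
                    for mode in config.match_modes:
                        acc = accepted[mode]
                        # smallest cutoff at which an accepted concept appears
                        first_hit = next(
                            (i + 1 for i, cid in enumerate(top_ids) if cid in acc),
                            None,
                        )
                        if first_hit is None:
                            continue
                        for kk in config.top_k:
                            if kk >= first_hit:
                                hits[(rule, kk, mode)] += 1
            for rule in rules:
                for kk in config.top_k:
                    for mode in config.match_modes:
                        cells[(k, rule, kk, mode)].append(
                            hits[(rule, kk, mode)] / len(groups)
                        )

    rows = []
    for (k, rule, kk, mode), per_case in sorted(cells.items()):
        n_groups = groups_per_case[k]
        rows.append(
            {
                "group_size": k,
                "rule": rule,
                "top_k": kk,
                "match_mode": mode,
                "stratum": stratum,
                "accuracy": sum(per_case) / len(per_case),
                "n_cases": len(per_case),
                "n_groups_per_case": sum(n_groups) / len(n_groups),
            }
        )
    return rows


def simulate(
    cases: Sequence[CaseRecord],
    graph: OntologyGraph,
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Run the full accuracy sweep; one row per
    (group size, rule, top-k, match mode, stratum) cell.

    Cases flagged excluded or empty are dropped first; cases with fewer
    users than a group size are skipped for that size only, keeping the
    denominators honest.
    """
    config = config or SimulationConfig()
    cases = _eligible(cases)
    if not cases:
        raise ValueError("no eligible cases to simulate")

    if config.stratify_by is None:
        rows = _simulate_stratum(cases, graph, config, stratum=None)
    elif config.stratify_by in ("specialty", "chief_complaint"):
        rows = []
        labels = sorted(
            {getattr(c, config.stratify_by) for c in cases}
            - {None}
        )
        for label in labels:
            subset = [c for c in cases if getattr(c, config.stratify_by) == label]
            if not subset:
                logger.warning("stratum %r has no cases; omitted", label)
                continue
            rows.extend(_simulate_stratum(subset, graph, config, stratum=label))
    elif config.stratify_by == "tenure":
        rows = []
        eligible = [c for c in cases if _has_tenure_depth(c, config)]
        if not eligible:
            raise ValueError(
                f"no case has >= {config.min_per_tenure} users of each tenure level"
            )
        for level in config.tenure_levels:
            rows.extend(
                _simulate_stratum(eligible, graph, config, stratum=level,
                                  user_filter=level)
            )
    else:
        raise ValueError(f"unknown stratification {config.stratify_by!r}")

    return pd.DataFrame(
        rows,
        columns=[
            "group_size", "rule", "top_k", "match_mode", "stratum",
            "accuracy", "n_cases", "n_groups_per_case",
        ],
    )


def _has_tenure_depth(case: CaseRecord, config: SimulationConfig) -> bool:
    """Does the case have enough mapped users at every compared tenure level?"""
    users_with_entries = {e.user_id for e in entries_from_case(case)}
    counts: dict[str, set[str]] = defaultdict(set)
    for r in case.responses:
        if r.user_id in users_with_entries and r.tenure is not None:
            counts[r.tenure].add(r.user_id)
    return all(
        len(counts.get(level, ())) >= config.min_per_tenure
        for level in config.tenure_levels
    )
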