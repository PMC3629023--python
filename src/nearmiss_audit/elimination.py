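"""Greedy stepwise elimination of inclusion criteria by frequency of use.

The procedure ranks criteria by how many of the identified cases they cover:
the most frequently used criterion is excluded and all remaining cases
carrying it are (temporarily) removed; frequencies are then recomputed among
the remaining cases and the process repeats until no case is left. Criteria
selected at some step with at least one remaining case have an *independent*
contribution — they identify cases no more-frequent criterion already
captured. Criteria whose remaining count hits zero before they are ever
selected are *passive*: they only ever fired alongside other criteria.
Criteria that never fired at all are reported separately as *unused*.

Ties are broken by the criterion's frequency in the original full cohort
(higher first), then by registry order. The per-step frequency snapshots are
sufficient statistics for the whole procedure: two matrices with the same
step marginals produce the same trace, which is why a case×criterion matrix
can be reconstructed from a published grid of per-step counts
(:func:`reconstruct_fixture_from_step_marginals`) and replayed exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "IncidenceMatrix",
    "EliminationStep",
    "EliminationTrace",
    "StepMarginals",
    "stepwise_elimination",
    "independent_contribution",
    "marginals_from_trace",
    "reconstruct_fixture_from_step_marginals",
    "trace_to_tsv",
]


@dataclass
class IncidenceMatrix:
    """Boolean case × criterion membership relation.

    Every case (row) must carry at least one criterion; an all-zero row would
    be a case included by no criterion and is rejected at construction.
    Criteria with zero occurrences (all-zero columns) are allowed — they are
    the "unused" criteria.
    """

    case_ids: list[str]
    criterion_ids: list[str]
    membership: np.ndarray  # bool, shape (n_cases, n_criteria)

    def __post_init__(self):
        self.membership = np.asarray(self.membership, dtype=bool)
        if self.membership.shape != (len(self.case_ids), len(self.criterion_ids)):
            raise ValueError("membership shape does not match id lists")
        if len(self.case_ids) and not self.membership.any(axis=1).all():
            bad = [
                self.case_ids[i]
                for i in np.flatnonzero(~self.membership.any(axis=1))
            ]
            raise ValueError(f"cases with no met criterion: {bad}")

    @property
    def n_cases(self) -> int:
        return len(self.case_ids)

    def column_counts(self) -> dict[str, int]:
        return dict(
            zip(self.criterion_ids, self.membership.sum(axis=0).astype(int).tolist())
        )


@dataclass
class EliminationStep:
    step_index: int  # 1-based
    selected_criterion: str
    cases_removed: int
    remaining_before: int
    remaining_after: int
    #: counts among the cases remaining *before* this step's removal, for
    #: every criterion not yet excluded
    frequency_snapshot: dict[str, int]


@dataclass
class EliminationTrace:
    criterion_ids: list[str]
    n_cases: int
    steps: list[EliminationStep]
    independent_criteria: list[tuple[str, int]]  # (criterion, count at selection)
    passive_criteria: list[str]
    unused_criteria: list[str]

    def to_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "steps": [
                {
                    "step_index": s.step_index,
                    "selected_criterion": s.selected_criterion,
                    "cases_removed": s.cases_removed,
                    "remaining_before": s.remaining_before,
                    "remaining_after": s.remaining_after,
                    "frequency_snapshot": dict(s.frequency_snapshot),
                }
                for s in self.steps
            ],
            "independent_criteria": [list(t) for t in self.independent_criteria],
            "passive_criteria": list(self.passive_criteria),
            "unused_criteria": list(self.unused_criteria),
        }


def stepwise_elimination(m: IncidenceMatrix) -> EliminationTrace:
    """Run the greedy frequency-ranked elimination until no cases remain."""
    n_cases, n_crit = m.membership.shape
    original_counts = m.membership.sum(axis=0)
    remaining = np.ones(n_cases, dtype=bool)
    excluded = np.zeros(n_crit, dtype=bool)
    steps: list[EliminationStep] = []
    independent: list[tuple[str, int]] = []
    step_index = 0
    while remaining.any():
        step_index += 1
        counts = m.membership[remaining].sum(axis=0)
        snapshot = {
            m.criterion_ids[j]: int(counts[j])
            for j in range(n_crit)
            if not excluded[j]
        }
        # argmax with tie-break: current count desc, original count desc, order
        best = None
        for j in range(n_crit):
            if excluded[j]:
                continue
            key = (counts[j], original_counts[j], -j)
            if best is None or key > best[0]:
                best = (key, j)
        j = best[1]
        sel = m.criterion_ids[j]
        removed_mask = remaining & m.membership[:, j]
        n_removed = int(removed_mask.sum())
        remaining_before = int(remaining.sum())
        remaining = remaining & ~removed_mask
        excluded[j] = True
        steps.append(
            EliminationStep(
                step_index=step_index,
                selected_criterion=sel,
                cases_removed=n_removed,
                remaining_before=remaining_before,
                remaining_after=int(remaining.sum()),
                frequency_snapshot=snapshot,
            )
        )
        independent.append((sel, n_removed))
    passive = [
        m.criterion_ids[j]
        for j in range(n_crit)
        if not excluded[j] and original_counts[j] > 0
    ]
    unused = [
        m.criterion_ids[j]
        for j in range(n_crit)
        if not excluded[j] and original_counts[j] == 0
    ]
    return EliminationTrace(
        criterion_ids=list(m.criterion_ids),
        n_cases=n_cases,
        steps=steps,
        independent_criteria=independent,
        passive_criteria=passive,
        unused_criteria=unused,
    )


def independent_contribution(trace: EliminationTrace) -> dict:
    """Partition of the criteria into independent / passive / unused."""
    return {
        "independent": list(trace.independent_criteria),
        "passive": list(trace.passive_criteria),
        "unused": list(trace.unused_criteria),
    }


@dataclass
class StepMarginals:
    """Per-step frequency grid, as a published elimination table prints it.

    ``counts[c][k]`` is the number of remaining cases carrying criterion
    ``c`` after ``k`` exclusion steps (column 0 = full cohort); ``None``
    stands for a dash (zero or already excluded). ``selected[k]`` lists the
    criteria excluded at step ``k+1`` — normally one, but a final batch of
    single-case criteria may be excluded simultaneously.
    """

    criterion_ids: list[str]
    n_remaining: list[int]
    counts: dict[str, list[Optional[int]]]
    selected: list[list[str]]

    @property
    def n_steps(self) -> int:
        return len(self.selected)


def _cnt(x: Optional[int]) -> int:
    return 0 if x is None else int(x)


def marginals_from_trace(trace: EliminationTrace) -> StepMarginals:
    """Express a trace as the step-marginal grid it uniquely determines."""
    n_steps = len(trace.steps)
    n_remaining = [trace.n_cases] + [s.remaining_after for s in trace.steps]
    excluded_at: dict[str, int] = {
        s.selected_criterion: s.step_index for s in trace.steps
    }
    counts: dict[str, list[Optional[int]]] = {}
    for c in trace.criterion_ids:
        col: list[Optional[int]] = []
        for k in range(n_steps + 1):
            if c in excluded_at and excluded_at[c] <= k:
                col.append(None)
            elif k < n_steps:
                col.append(trace.steps[k].frequency_snapshot[c])
            else:
                col.append(0)
        counts[c] = col
    selected = [[s.selected_criterion] for s in trace.steps]
    return StepMarginals(
        criterion_ids=list(trace.criterion_ids),
        n_remaining=n_remaining,
        counts=counts,
        selected=selected,
    )


def reconstruct_fixture_from_step_marginals(
    marginals: StepMarginals, case_id_prefix: str = "case"
) -> IncidenceMatrix:
    """Build SOME incidence matrix whose elimination replays the marginals.

    Cases removed at step k all carry the step-k selected criterion (tiled
    across the removed block when several criteria are excluded at once); for
    every other criterion, the drop in its count between consecutive columns
    says how many step-k cases also carry it, and those occurrences are
    assigned to the first cases of the block (first-fit by case index). The
    result is deterministic; inconsistent marginals raise a ValueError naming
    the violated delta.
    """
    S = marginals.n_steps
    if len(marginals.n_remaining) != S + 1:
        raise ValueError("n_remaining must have one entry per column")
    if marginals.n_remaining[-1] != 0:
        raise ValueError("elimination must end with zero remaining cases")
    for c in marginals.criterion_ids:
        if len(marginals.counts[c]) != S + 1:
            raise ValueError(f"criterion {c!r}: wrong number of columns")

    n_cases = marginals.n_remaining[0]
    n_crit = len(marginals.criterion_ids)
    col_of = {c: j for j, c in enumerate(marginals.criterion_ids)}
    membership = np.zeros((n_cases, n_crit), dtype=bool)
    offset = 0
    excluded: set[str] = set()
    for k in range(1, S + 1):
        removed = marginals.n_remaining[k - 1] - marginals.n_remaining[k]
        if removed <= 0:
            raise ValueError(f"step {k}: non-positive number of removed cases")
        sel = marginals.selected[k - 1]
        sel_counts = [_cnt(marginals.counts[s][k - 1]) for s in sel]
        if sum(sel_counts) != removed:
            raise ValueError(
                f"step {k}: selected criteria cover {sum(sel_counts)} cases "
                f"but {removed} are removed"
            )
        # tile the selected criteria across the removed block
        pos = offset
        for s, c_s in zip(sel, sel_counts):
            membership[pos : pos + c_s, col_of[s]] = True
            pos += c_s
            excluded.add(s)
        # co-occurring criteria: first-fit within the block
        for c in marginals.criterion_ids:
            if c in sel or c in excluded:
                continue
            delta = _cnt(marginals.counts[c][k - 1]) - _cnt(marginals.counts[c][k])
            if delta < 0 or delta > removed:
                raise ValueError(
                    f"step {k}: criterion {c!r} count delta {delta} outside "
                    f"[0, {removed}]"
                )
            membership[offset : offset + delta, col_of[c]] = True
        offset += removed
    if offset != n_cases:
        raise ValueError(
            f"steps remove {offset} cases but the cohort holds {n_cases}"
        )
    case_ids = [f"{case_id_prefix}-{i:03d}" for i in range(n_cases)]
    return IncidenceMatrix(case_ids, list(marginals.criterion_ids), membership)


def trace_to_tsv(trace: EliminationTrace) -> str:
    """Render a trace as a criteria × steps grid with EXCL markers and dashes."""
    marg = marginals_from_trace(trace)
    excluded_at = {s.selected_criterion: s.step_index for s in trace.steps}
    header = ["criterion", f"all n={trace.n_cases}"] + [
        f"step{s.step_index} n={s.remaining_after}" for s in trace.steps
    ]
    lines = ["\t".join(header)]
    for c in trace.criterion_ids:
        cells = []
        for k in range(marg.n_steps + 1):
            if excluded_at.get(c) == k:
                cells.append("EXCL")
            else:
                v = marg.counts[c][k]
                cells.append("-" if not v else str(v))
        lines.append("\t".join([c] + cells))
    return "\n".join(lines) + "\n"
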