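"""Distance-gated optimal spot pairing across two channels.

Pairing is a linear assignment (Hungarian) on the padded cost matrix: real
pairs cost their Euclidean distance when within the gate, and leaving a spot
unmatched costs ``gate_radius``, so the solver minimizes

    sum(pair distances) + gate_radius * (n unmatched A + n unmatched B)

over matchings whose every pair lies within the gate.  This is the
"pair everything pairable" reading of an assignment-based co-localization
call; per-cell fractions, compartment splits, and group comparisons follow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .errors import ConsistencyError, ValidationError


@dataclass(frozen=True)
class MatchResult:
    """Matched pairs and leftovers for one cell's two spot sets."""

    cell_id: int | None
    pairs: tuple[tuple[int, int, float], ...]  # (index_a, index_b, distance µm)
    unmatched_a: tuple[int, ...]
    unmatched_b: tuple[int, ...]
    gate_radius: float

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def total_cost(self) -> float:
        return float(sum(d for _, _, d in self.pairs))

    def padded_cost(self) -> float:
        return self.total_cost() + self.gate_radius * (
            len(self.unmatched_a) + len(self.unmatched_b)
        )


def _positions(spots) -> np.ndarray:
    if len(spots) == 0:
        return np.zeros((0, 3))
    if hasattr(spots[0], "position"):
        return np.asarray([s.position for s in spots], dtype=float)
    return np.asarray(spots, dtype=float)


def match_spots(spots_a, spots_b, gate_radius: float, cell_id=None) -> MatchResult:
    """Optimal gated pairing of two spot sets (positions or Spot objects).

    Pairs are reported sorted by ascending (index_a, index_b); every pair
    distance is <= gate_radius.
    """
    if gate_radius <= 0:
        raise ValidationError("gate_radius must be > 0")
    pa, pb = _positions(spots_a), _positions(spots_b)
    na, nb = len(pa), len(pb)
    if na == 0 or nb == 0:
        return MatchResult(
            cell_id=cell_id,
            pairs=(),
            unmatched_a=tuple(range(na)),
            unmatched_b=tuple(range(nb)),
            gate_radius=float(gate_radius),
        )

    dist = cdist(pa, pb)
    big = gate_radius * (na + nb + 2) + 1.0
    n = na + nb
    cost = np.zeros((n, n))
    cost[:na, :nb] = np.where(dist <= gate_radius, dist, big)
    cost[:na, nb:] = gate_radius
    cost[na:, :nb] = gate_radius
    rows, cols = linear_sum_assignment(cost)

    pairs, un_a, un_b = [], set(range(na)), set(range(nb))
    for i, j in zip(rows, cols):
        if i < na and j < nb and dist[i, j] <= gate_radius:
            pairs.append((int(i), int(j), float(dist[i, j])))
            un_a.discard(i)
            un_b.discard(j)
    pairs.sort()
    return MatchResult(
        cell_id=cell_id,
        pairs=tuple(pairs),
        unmatched_a=tuple(sorted(un_a)),
        unmatched_b=tuple(sorted(un_b)),
        gate_radius=float(gate_radius),
    )


def coloc_fraction(match: MatchResult, n_reference: int) -> float:
    """Matched share of the reference channel: |pairs| / n_reference.

    Returns NaN (cell excluded from summaries) when the reference channel is
    empty; raises if bookkeeping is inconsistent.
    """
    if n_reference == 0:
        return float("nan")
    if n_reference < match.n_pairs:
        raise ConsistencyError(
            f"{match.n_pairs} pairs but only {n_reference} reference spots"
        )
    return match.n_pairs / n_reference


@dataclass(frozen=True)
class ColocSummary:
    per_cell_fraction: tuple[float, ...]
    reference_channel: str
    mean: float
    sem: float  # NaN when n == 1
    n_cells: int
    nuclear_share: float
    cytoplasmic_share: float


def summarize(
    per_cell, compartment_pairs=None, reference_channel: str = "A"
) -> ColocSummary:
    """Mean ± SEM of defined per-cell fractions, plus compartment shares.

    ``compartment_pairs`` is an optional {"nuclear": n, "cytoplasmic": n}
    count of matched pairs; shares are NaN when absent or all-zero.
    """
    vals = np.asarray([v for v in per_cell if not math.isnan(v)], dtype=float)
    if vals.size == 0:
        raise ValidationError("no defined per-cell fractions to summarize")
    if np.any((vals < 0) | (vals > 1)):
        raise ValidationError("per-cell fractions must lie in [0, 1]")
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else float("nan")

    nuc_share = cyto_share = float("nan")
    if compartment_pairs:
        nuc = float(compartment_pairs.get("nuclear", 0))
        cyto = float(compartment_pairs.get("cytoplasmic", 0))
        total = nuc + cyto
        if total > 0:
            nuc_share, cyto_share = nuc / total, cyto / total
    return ColocSummary(
        per_cell_fraction=tuple(float(v) for v in vals),
        reference_channel=reference_channel,
        mean=mean,
        sem=sem,
        n_cells=len(vals),
        nuclear_share=nuc_share,
        cytoplasmic_share=cyto_share,
    )


def compare_groups(group1, group2):
    """Welch (unequal-variance) unpaired two-sided t-test.

    Returns (t, df, p).  Degenerate zero-variance cases follow stated
    conventions: equal constant groups give (0, df, 1); separated constant
    groups give t = ±inf, p = 0.
    """
    a = np.asarray(list(group1), dtype=float)
    b = np.asarray(list(group2), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    df_welch = len(a) + len(b) - 2  # fallback df for degenerate cases
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(df_welch), 1.0
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return sign * float("inf"), float(df_welch), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def chance_coloc_expectation(spot_density: float, gate_radius: float) -> float:
    """Probability a reference spot has >= 1 Poisson-background partner
    within the gate: 1 - exp(-density * (4/3) * pi * r^3)."""
    if spot_density < 0:
        raise ValidationError("spot_density must be >= 0")
    if gate_radius < 0:
        raise ValidationError("gate_radius must be >= 0")
    return 1.0 - math.exp(-spot_density * (4.0 / 3.0) * math.pi * gate_radius**3)


# --------------------------------------------------------------------------- #
# per-cell pipeline over spot tables
# --------------------------------------------------------------------------- #


def colocalize_cells(
    spots_a, spots_b, gate_radius: float = 0.3, reference: str = "A"
) -> tuple[pd.DataFrame, ColocSummary]:
    """Group two Spot sequences by cell, match per cell, and summarize.

    Matching never crosses cell boundaries; cells with zero reference spots
    are excluded from the summary.  Returns a per-cell frame with columns
    (cell_id, n_a, n_b, n_pairs, fraction, nuclear_pairs, cytoplasmic_pairs)
    and the cohort summary.
    """
    if reference not in ("A", "B"):
        raise ValidationError("reference must be 'A' or 'B'")

    def by_cell(spots):
        d: dict[int, list] = {}
        for s in spots:
            if s.cell_id is not None:
                d.setdefault(int(s.cell_id), []).append(s)
        return d

    cells_a, cells_b = by_cell(spots_a), by_cell(spots_b)
    rows = []
    comp_totals = {"nuclear": 0, "cytoplasmic": 0}
    for cid in sorted(set(cells_a) | set(cells_b)):
        sa = cells_a.get(cid, [])
        sb = cells_b.get(cid, [])
        match = match_spots(sa, sb, gate_radius, cell_id=cid)
        n_ref = len(sa) if reference == "A" else len(sb)
        frac = coloc_fraction(match, n_ref)
        nuc = cyto = 0
        for ia, ib, _ in match.pairs:
            ref_spot = sa[ia] if reference == "A" else sb[ib]
            if ref_spot.compartment == "nuclear":
                nuc += 1
            elif ref_spot.compartment == "cytoplasmic":
                cyto += 1
        comp_totals["nuclear"] += nuc
        comp_totals["cytoplasmic"] += cyto
        rows.append(
            {
                "cell_id": cid,
                "n_a": len(sa),
                "n_b": len(sb),
                "n_pairs": match.n_pairs,
                "fraction": frac,
                "nuclear_pairs": nuc,
                "cytoplasmic_pairs": cyto,
            }
        )
    per_cell = pd.DataFrame(
        rows,
        columns=[
            "cell_id", "n_a", "n_b", "n_pairs", "fraction",
            "nuclear_pairs", "cytoplasmic_pairs",
        ],
    )
    summary = summarize(
        per_cell["fraction"].tolist() if len(per_cell) else [],
        comp_totals if sum(comp_totals.values()) else None,
        reference_channel=reference,
    )
    return per_cell, summary
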