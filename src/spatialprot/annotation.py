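"""Ranked-list enrichment via the minimal-hypergeometric statistic with exact
p-values, and compartment-level fold-change shift testing."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import AnnotationSet


# ---------------------------------------------------------------------------
# Minimal hypergeometric statistic
# ---------------------------------------------------------------------------

@dataclass
class MHGResult:
    term_id: str
    direction: str
    N: int
    B: int
    b_star: int
    n_star: int
    s: float
    p_exact: float


def mhg_statistic(membership) -> tuple[float, int, int]:
    """Minimal hypergeometric statistic of an ordered boolean vector.

    s = min over prefix lengths n in [1, N-1] of the hypergeometric upper
    tail P(X >= b(n) | N, B, n), where b(n) is the cumulative member count.
    Ties are broken toward the smallest n.  Returns (s, n_star, b_star).
    """
    v = np.asarray(membership, dtype=bool)
    N = len(v)
    if N < 1:
        raise ValueError("membership vector must have length >= 1")
    B = int(v.sum())
    if B == 0:
        raise ValueError("membership vector has no true entries")
    if N == 1:
        return 1.0, 1, B
    ns = np.arange(1, N)
    bs = np.cumsum(v)[: N - 1]
    tails = stats.hypergeom.sf(bs - 1, N, B, ns)
    i = int(np.argmin(tails))  # argmin returns the first minimum: smallest n
    return float(tails[i]), int(ns[i]), int(bs[i])


def mhg_exact_pvalue(s: float, N: int, B: int) -> float:
    """Exact p-value of the mHG statistic: the probability, under a uniform
    random permutation of the membership vector, that the statistic is <= s.

    Dynamic programming over the (n, b) lattice tracks the probability of the
    sequential urn process reaching each cell without having entered the
    rejection region {(n, b): HGT(n, b) <= s, 1 <= n <= N-1}; mass entering
    the region is accumulated into the p-value.  Working with aggregated cell
    probabilities (not path counts) keeps all quantities in [0, 1], so no
    log-space rescaling is needed.  O(N*B) time.
    """
    if not 1 <= B <= N:
        raise ValueError("need 1 <= B <= N")
    if s >= 1.0:
        return 1.0
    # rejection boundary per n: smallest b with upper tail <= s
    tol = 1.0 + 1e-12
    b_crit = np.full(N + 1, B + 1, dtype=int)
    for n in range(1, N):
        bs = np.arange(0, min(B, n) + 1)
        tails = stats.hypergeom.sf(bs - 1, N, B, n)
        hit = np.nonzero(tails <= s * tol)[0]
        if hit.size:
            b_crit[n] = int(bs[hit[0]])

    w = np.zeros(B + 1)
    w[0] = 1.0
    p_reject = 0.0
    for n in range(N):
        w_new = np.zeros(B + 1)
        bmax = min(B, n)
        for b in range(bmax + 1):
            if w[b] == 0.0:
                continue
            remaining = N - n
            p_member = (B - b) / remaining
            if p_member > 0:
                w_new[b + 1] += w[b] * p_member
            w_new[b] += w[b] * (1.0 - p_member)
        # arriving at column n+1: absorb mass that enters the rejection region
        if 1 <= n + 1 <= N - 1:
            crit = b_crit[n + 1]
            if crit <= B:
                p_reject += float(w_new[crit:].sum())
                w_new[crit:] = 0.0
        w = w_new
    return min(1.0, p_reject)


def ranked_enrichment(
    ranking: list[str],
    gene_sets: dict[str, set[str]],
    p_threshold: float = 1e-3,
    directions: str = "both",
    min_members: int = 3,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Score every gene set against a fold-change-ranked protein list.

    Each term is scored on the ranking and (for ``directions="both"``) on its
    reverse, so both up- and down-enrichment are reported.  Only results with
    exact p-value strictly below ``p_threshold`` are returned.  Terms with
    fewer than ``min_members`` members inside the ranked universe are skipped
    and reported with a reason.
    """
    if directions not in ("both", "up", "down"):
        raise ValueError(f"invalid directions {directions!r}")
    universe = list(ranking)
    index = {p: i for i, p in enumerate(universe)}
    if len(index) != len(universe):
        raise ValueError("ranking contains duplicate proteins")
    N = len(universe)
    rows: list[MHGResult] = []
    skipped: list[tuple[str, str]] = []
    wanted = ("up", "down") if directions == "both" else (directions,)
    for term, members in gene_sets.items():
        inside = members & index.keys()
        if not inside:
            skipped.append((term, "no members in ranked universe"))
            continue
        if len(inside) < min_members:
            skipped.append((term, f"only {len(inside)} members in universe"))
            continue
        v = np.zeros(N, dtype=bool)
        v[[index[p] for p in inside]] = True
        for direction in wanted:
            vec = v if direction == "up" else v[::-1]
            s, n_star, b_star = mhg_statistic(vec)
            p = mhg_exact_pvalue(s, N, int(v.sum()))
            if p < p_threshold:
                rows.append(
                    MHGResult(
                        term_id=term, direction=direction, N=N, B=int(v.sum()),
                        b_star=b_star, n_star=n_star, s=s, p_exact=p,
                    )
                )
    table = pd.DataFrame(
        [r.__dict__ for r in rows],
        columns=["term_id", "direction", "N", "B", "b_star", "n_star", "s", "p_exact"],
    )
    if len(table):
        table = table.sort_values(
            ["p_exact", "term_id", "direction"], kind="stable"
        ).reset_index(drop=True)
    return table, skipped


# ---------------------------------------------------------------------------
# Compartment shift
# ---------------------------------------------------------------------------

@dataclass
class ShiftResult:
    compartment: str
    n_in: int
    n_out: int
    median_shift: float
    p_value: float


def compartment_shift(
    fold_changes: dict[str, float],
    annotations: AnnotationSet,
    compartment: str,
    min_group: int = 5,
) -> ShiftResult:
    """Two-sided Wilcoxon rank-sum comparison of fold changes inside vs
    outside a subcellular compartment, with tie correction (normal
    approximation).  ``median_shift`` = median(in) - median(out)."""
    members = annotations.proteins_in_compartment(compartment)
    fc_in = np.array([v for p, v in fold_changes.items() if p in members])
    fc_out = np.array([v for p, v in fold_changes.items() if p not in members])
    if len(fc_in) < min_group or len(fc_out) < min_group:
        raise ValueError(
            f"need >= {min_group} proteins in and out of {compartment!r}; "
            f"got {len(fc_in)} in, {len(fc_out)} out"
        )
    res = stats.mannwhitneyu(fc_in, fc_out, alternative="two-sided", method="asymptotic")
    return ShiftResult(
        compartment=compartment,
        n_in=len(fc_in),
        n_out=len(fc_out),
        median_shift=float(np.median(fc_in) - np.median(fc_out)),
        p_value=float(res.pvalue),
    )
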