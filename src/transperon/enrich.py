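"""Pulldown enrichment scoring.

Two deliberately separate computations mirror the analysis's two outputs:

* heatmap path — log2(TPM + 1) per sample minus the (log-scale averaged)
  control, exported as an ordered matrix; and
* differential path — a fixed-dispersion negative-binomial exact test on
  counts (variance = mu + dispersion * mu^2, default dispersion 0.1), BH FDR,
  and the "fold >= 4 and FDR < 0.001" enrichment filter, with fold changes on
  size-factor-normalized counts plus a 0.5 prior count per group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .errors import ValidationError

PULLDOWN = "pulldown"
CONTROL = "control"


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with sample role tags.

    ``values``: DataFrame (genes x samples), non-negative.
    ``roles``: sample name -> {"pulldown", "control"}.
    ``unit``: "counts" or "tpm".
    """

    values: pd.DataFrame
    roles: dict[str, str]
    unit: str = "counts"

    def __post_init__(self):
        if self.values.index.has_duplicates:
            raise ValidationError("gene labels must be unique")
        if (self.values.values < 0).any():
            raise ValidationError("expression values must be non-negative")
        if self.unit not in ("counts", "tpm"):
            raise ValidationError("unit must be 'counts' or 'tpm'")
        unknown = set(self.roles) - set(self.values.columns)
        if unknown:
            raise ValidationError(f"roles reference unknown samples: {sorted(unknown)}")
        bad = {r for r in self.roles.values() if r not in (PULLDOWN, CONTROL)}
        if bad:
            raise ValidationError(f"unknown sample roles: {sorted(bad)}")
        if CONTROL not in self.roles.values():
            raise ValidationError("at least one control sample is required")

    @property
    def pulldown_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.roles.get(s) == PULLDOWN]

    @property
    def control_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.roles.get(s) == CONTROL]


def log_enrichment(matrix: ExpressionMatrix) -> pd.DataFrame:
    """log2(TPM + 1) per pulldown sample minus the control on the log scale.

    Multiple controls are averaged on the log scale first.  Requires TPM-unit
    input and at least one pulldown sample.
    """
    if matrix.unit != "tpm":
        raise ValidationError("log_enrichment expects TPM-unit values")
    pulls = matrix.pulldown_samples
    if not pulls:
        raise ValidationError("no pulldown samples in matrix")
    logv = np.log2(matrix.values + 1.0)
    ctrl = logv[matrix.control_samples].mean(axis=1)
    return logv[pulls].sub(ctrl, axis=0)


def _nb_logpmf(k, mean, dispersion):
    if dispersion == 0:
        return stats.poisson.logpmf(k, mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return stats.nbinom.logpmf(k, r, p)


def nb_exact_test(
    count_a: int,
    count_b: int,
    size_factor_a: float = 1.0,
    size_factor_b: float = 1.0,
    dispersion: float = 0.1,
    n_a: int = 1,
    n_b: int = 1,
) -> float:
    """Two-sided exact test for a two-group count split at fixed dispersion.

    ``count_a``/``count_b`` are group sums over ``n_a``/``n_b`` libraries
    (both 1 for the single-library design); size factors are per-library
    depths.  Counts are first scaled to a common effective per-library size
    (the geometric mean of the size factors) and rounded.  Conditional on the
    scaled total t, the per-library mean is mu = t / (n_a + n_b) and the
    group-A sum follows NB(n_a * mu, dispersion / n_a) — the sum of n iid NB
    variables keeps variance = m + (phi/n) m^2 in the group mean m.  The
    two-sided p-value sums the conditional weights of all outcomes no more
    probable than the observed one.  dispersion == 0 reduces to the
    Poisson-conditional (binomial) exact test.
    """
    if dispersion < 0:
        raise ValidationError("dispersion must be >= 0")
    if size_factor_a <= 0 or size_factor_b <= 0:
        raise ValidationError("size factors must be > 0")
    if count_a < 0 or count_b < 0:
        raise ValidationError("counts must be >= 0")
    if n_a < 1 or n_b < 1:
        raise ValidationError("group sizes must be >= 1")

    common = math.sqrt(size_factor_a * size_factor_b)
    ya = int(round(count_a * common / size_factor_a))
    yb = int(round(count_b * common / size_factor_b))
    total = ya + yb
    if total == 0:
        return 1.0

    mu = total / (n_a + n_b)
    y = np.arange(total + 1)
    logw = _nb_logpmf(y, n_a * mu, dispersion / n_a) + _nb_logpmf(
        total - y, n_b * mu, dispersion / n_b
    )
    logw -= logsumexp(logw)
    # include all outcomes whose probability <= observed (small relative slack
    # so exact symmetric twins are never lost to rounding)
    keep = logw <= logw[ya] + 1e-8
    return float(min(1.0, np.exp(logsumexp(logw[keep]))))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, order-preserving and capped at 1."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def enrichment_table(
    matrix: ExpressionMatrix,
    pulldown: str | list[str] | None = None,
    dispersion: float = 0.1,
    min_fold: float = 4.0,
    max_fdr: float = 0.001,
) -> pd.DataFrame:
    """Per-gene enrichment statistics for a pulldown group vs pooled control.

    ``pulldown`` may be one sample name or a list of replicate sample names
    (default: the first pulldown sample); all control samples form the other
    group.  Counts input: size factors are total-count scaling per library;
    fold change uses normalized per-library mean counts with a 0.5 prior per
    group; p-values come from :func:`nb_exact_test` and FDR from
    :func:`bh_fdr`.  TPM input bypasses size-factor logic.
    Columns: enrichment, fold_change, p_value, fdr, enriched.
    """
    pulls = matrix.pulldown_samples
    if not pulls:
        raise ValidationError("no pulldown samples in matrix")
    if pulldown is None:
        group_pull = pulls[:1]
    elif isinstance(pulldown, str):
        group_pull = [pulldown]
    else:
        group_pull = list(pulldown)
    bad = [s for s in group_pull if s not in pulls]
    if bad:
        raise ValidationError(f"not pulldown sample(s): {bad}")

    n_pull, n_ctrl = len(group_pull), len(matrix.control_samples)
    pull = matrix.values[group_pull].sum(axis=1).to_numpy(dtype=float)
    ctrl = matrix.values[matrix.control_samples].sum(axis=1).to_numpy(dtype=float)

    if matrix.unit == "counts":
        sf_pull = pull.sum() / n_pull  # per-library depth of each group
        sf_ctrl = ctrl.sum() / n_ctrl
        if sf_pull <= 0 or sf_ctrl <= 0:
            raise ValidationError("library sizes must be positive")
        mean_lib = math.sqrt(sf_pull * sf_ctrl)
        sf_pull /= mean_lib
        sf_ctrl /= mean_lib
    else:
        sf_pull = sf_ctrl = 1.0

    norm_pull = pull / (sf_pull * n_pull)  # normalized per-library means
    norm_ctrl = ctrl / (sf_ctrl * n_ctrl)
    fold = (norm_pull + 0.5) / (norm_ctrl + 0.5)
    enr = np.log2(norm_pull + 1.0) - np.log2(norm_ctrl + 1.0)

    pvals = np.array(
        [
            nb_exact_test(
                int(round(a)), int(round(b)), sf_pull, sf_ctrl, dispersion,
                n_a=n_pull, n_b=n_ctrl,
            )
            for a, b in zip(pull, ctrl)
        ]
    )
    fdr = bh_fdr(pvals)
    table = pd.DataFrame(
        {
            "enrichment": enr,
            "fold_change": fold,
            "p_value": pvals,
            "fdr": fdr,
        },
        index=matrix.values.index,
    )
    table["enriched"] = (table["fold_change"] >= min_fold) & (table["fdr"] < max_fdr)
    return table


def apply_enrichment_filter(
    table: pd.DataFrame, min_fold: float = 4.0, max_fdr: float = 0.001
) -> list[str]:
    """Genes with fold_change >= min_fold ("at least fourfold") and fdr < max_fdr."""
    if len(table) == 0:
        return []
    sel = (table["fold_change"] >= min_fold) & (table["fdr"] < max_fdr)
    return list(table.index[sel])


def heatmap_matrix(enrichment: pd.DataFrame, gene_subset) -> pd.DataFrame:
    """Restrict/order the enrichment table rows to ``gene_subset``.

    Values are unchanged; unknown or empty subsets are validation errors.
    """
    subset = list(gene_subset)
    if not subset:
        raise ValidationError("gene_subset must be non-empty")
    unknown = [g for g in subset if g not in enrichment.index]
    if unknown:
        raise ValidationError(f"unknown gene labels: {unknown[:5]}")
    return enrichment.loc[subset]
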