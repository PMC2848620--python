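"""Group differences in cross-region synchrony: gains and losses.

The comparison asks, gene by gene, whether the cross-region correlation in
the case group differs from the control group. To keep power, only genes
with high synchrony in at least one condition (|r| above a cutoff, default
0.7) are tested. Significance of the shift comes from a percentile
bootstrap: subjects are resampled with replacement independently within
each group, the difference in genewise r is recorded per resample, and the
two-sided p is read off the empirical distribution. Benjamini-Hochberg
FDR control is applied over the selected genes, and significant genes whose
synchrony moves between a high band and a low band are labeled ``gain``
(low in controls, high in cases) or ``loss`` (high in controls, low in
cases); labels track the magnitude |r|, so a gene acquiring strong
*negative* synchrony also counts as a gain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._stats import (
    block_sizes,
    canonical_subject_order,
    resample_rvalues,
    stream_key,
)
from .datamodel import AnalysisConfig, InferenceError, PairedDataset, ValidationError
from .synchrony import genewise_synchrony

__all__ = [
    "select_high_synchrony_genes",
    "bootstrap_diff_pvalues",
    "bh_fdr",
    "classify_gain_loss",
    "run_differential_pipeline",
    "DifferentialResult",
]

logger = logging.getLogger(__name__)

LABEL_GAIN = "gain"
LABEL_LOSS = "loss"
LABEL_NONE = "not_classified"


def select_high_synchrony_genes(
    r_ctrl: np.ndarray, r_case: np.ndarray, cutoff: float = 0.7
) -> np.ndarray:
    """Indices of genes with |r| >= cutoff in at least one condition.

    A NaN correlation (degenerate gene) is ignored on its own side; a gene
    degenerate in both groups never qualifies.
    """
    r_ctrl = np.asarray(r_ctrl, dtype=float)
    r_case = np.asarray(r_case, dtype=float)
    if r_ctrl.shape != r_case.shape:
        raise ValidationError("r_ctrl and r_case must align to the same gene list")
    best = np.fmax(np.abs(r_ctrl), np.abs(r_case))  # fmax skips NaN sides
    return np.flatnonzero(np.nan_to_num(best, nan=-np.inf) >= cutoff)


def _dataset_stream(config: AnalysisConfig, data: PairedDataset) -> np.random.Generator:
    # Key the resample stream to the dataset's subject identity (not to the
    # argument position), so swapping ctrl/case arguments swaps the streams
    # with them and the difference statistic negates exactly.
    ident = ",".join(sorted(map(str, data.subject_ids)))
    return np.random.default_rng(stream_key([config.rng_seed, "diff", ident]))


def bootstrap_diff_pvalues(
    ctrl: PairedDataset,
    case: PairedDataset,
    genes: np.ndarray,
    config: AnalysisConfig,
) -> np.ndarray:
    """Two-sided percentile-bootstrap p-values for the synchrony shift.

    For each of ``config.n_bootstrap`` resamples, subjects are drawn with
    replacement independently within each group (each group keeps its own
    A/B pairing); the genewise difference ``delta = r_case - r_ctrl`` is
    recorded, and ``p = 2 * min(P(delta <= 0), P(delta >= 0))``, floored at
    ``1 / (n_bootstrap + 1)`` and capped at 1. Resamples where either
    group's r is degenerate are excluded from that gene's tally (counts
    logged). When ``config.detrend_age`` is set, both groups are
    age-detrended inside every resample. Deterministic given
    ``config.rng_seed``; invariant to gene order and subject column order.
    """
    if not np.array_equal(ctrl.gene_ids, case.gene_ids):
        raise ValidationError("ctrl and case must share the same gene universe")
    if ctrl.n_subjects < 4 or case.n_subjects < 4:
        raise InferenceError("each group needs at least 4 subjects")
    genes = np.asarray(genes, dtype=int)
    detrend = config.detrend_age
    B = config.n_bootstrap

    parts = []
    for data in (ctrl, case):
        order = canonical_subject_order(data.subject_ids)
        rng = _dataset_stream(config, data)
        n = data.n_subjects
        parts.append(
            dict(
                A=data.region_a.values[np.ix_(genes, order)],
                Bm=data.region_b.values[np.ix_(genes, order)],
                ages=data.ages[order] if detrend else None,
                idx=rng.integers(0, n, size=(B, n)),
            )
        )

    G = len(genes)
    n_le = np.zeros(G, dtype=np.int64)
    n_ge = np.zeros(G, dtype=np.int64)
    n_ok = np.zeros(G, dtype=np.int64)
    n_max = max(ctrl.n_subjects, case.n_subjects)
    g_block, c_block = block_sizes(G, B, n_max)
    for g0 in range(0, G, g_block):
        gsl = slice(g0, min(g0 + g_block, G))
        for c0 in range(0, B, c_block):
            csl = slice(c0, min(c0 + c_block, B))
            r_c = resample_rvalues(
                parts[0]["A"][gsl], parts[0]["Bm"][gsl], parts[0]["idx"][csl],
                ages=parts[0]["ages"], detrend=detrend,
            )
            r_k = resample_rvalues(
                parts[1]["A"][gsl], parts[1]["Bm"][gsl], parts[1]["idx"][csl],
                ages=parts[1]["ages"], detrend=detrend,
            )
            delta = r_k - r_c
            ok = np.isfinite(delta)
            n_ok[gsl] += ok.sum(axis=1)
            n_le[gsl] += ((delta <= 0) & ok).sum(axis=1)
            n_ge[gsl] += ((delta >= 0) & ok).sum(axis=1)

    dropped = int(B * G - n_ok.sum())
    if dropped:
        logger.info("bootstrap_diff_pvalues: excluded %d degenerate resample deltas", dropped)
    floor = 1.0 / (B + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = 2.0 * np.minimum(n_le, n_ge) / np.where(n_ok > 0, n_ok, 1)
    p = np.clip(p, floor, 1.0)
    p[n_ok == 0] = np.nan
    return p


def bh_fdr(pvalues: np.ndarray, q: float):
    """Benjamini-Hochberg step-up FDR control.

    Returns ``(q_values, significant)`` where ``q_values[i]`` is the
    adjusted value ``min_{j >= i} m * p_(j) / j`` (capped at 1) mapped back
    to input order, and ``significant`` is the boolean rejection mask at
    level ``q``. Empty input yields empty outputs.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    if not (0 < q < 1):
        raise ValidationError("q must be in (0, 1)")
    reject, q_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return q_adj, reject


def classify_gain_loss(
    r_ctrl: np.ndarray,
    r_case: np.ndarray,
    significant: np.ndarray,
    high: float = 0.7,
    low: float = 0.2,
) -> np.ndarray:
    """Label significant genes as gain/loss of synchrony by |r| bands.

    loss: |r_ctrl| >= high and |r_case| <= low (synchronized in controls,
    desynchronized in cases); gain: the reverse. Everything else — including
    significant shifts that stay inside the bands — is ``not_classified``
    but keeps its p and q downstream.
    """
    if not low < high:
        raise ValidationError("low threshold must be below high threshold")
    r_ctrl = np.abs(np.asarray(r_ctrl, dtype=float))
    r_case = np.abs(np.asarray(r_case, dtype=float))
    significant = np.asarray(significant, dtype=bool)
    labels = np.full(r_ctrl.shape, LABEL_NONE, dtype=object)
    with np.errstate(invalid="ignore"):
        loss = significant & (r_ctrl >= high) & (r_case <= low)
        gain = significant & (r_case >= high) & (r_ctrl <= low)
    labels[loss] = LABEL_LOSS
    labels[gain] = LABEL_GAIN
    return labels


@dataclass
class DifferentialResult:
    """Per-selected-gene shift estimates plus a gain/loss count summary."""

    gene_ids: np.ndarray  # selected genes only
    r_ctrl: np.ndarray
    r_case: np.ndarray
    delta: np.ndarray  # r_case - r_ctrl
    p_boot: np.ndarray
    q_bh: np.ndarray
    label: np.ndarray
    n_genes_tested: int  # size of the full gene universe
    fdr_grid_counts: pd.DataFrame  # columns: fdr_q, n_significant, n_gain, n_loss
    config: AnalysisConfig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "r_ctrl": self.r_ctrl,
                "r_case": self.r_case,
                "delta": self.delta,
                "p_boot": self.p_boot,
                "q_bh": self.q_bh,
                "label": self.label,
            }
        )

    def manifest(self) -> dict:
        return {
            "config": asdict(self.config),
            "n_genes_tested": int(self.n_genes_tested),
            "n_selected": int(len(self.gene_ids)),
        }


def run_differential_pipeline(
    ctrl: PairedDataset,
    case: PairedDataset,
    config: AnalysisConfig,
    select_all: bool = False,
    fdr_grid: tuple[float, ...] = (0.05, 0.1, 0.2, 0.3),
) -> DifferentialResult:
    """Full control-vs-case synchrony comparison.

    Stages: genewise r per group -> high-synchrony selection (skipped when
    ``select_all``, for sensitivity analysis) -> per-gene bootstrap p for
    the shift -> BH adjustment over the selected genes -> gain/loss
    labeling at ``config.fdr_q``. The summary table reports significant /
    gain / loss counts over ``fdr_grid``.
    """
    if not np.array_equal(ctrl.gene_ids, case.gene_ids):
        raise ValidationError("ctrl and case must share the same gene universe")
    r_ctrl_all = genewise_synchrony(ctrl)
    r_case_all = genewise_synchrony(case)
    if select_all:
        sel = np.flatnonzero(np.isfinite(r_ctrl_all) & np.isfinite(r_case_all))
    else:
        sel = select_high_synchrony_genes(
            r_ctrl_all, r_case_all, config.selection_cutoff
        )
    logger.info(
        "differential: %d of %d genes selected at |r| >= %.2f",
        len(sel), len(r_ctrl_all), config.selection_cutoff,
    )
    r_ctrl = r_ctrl_all[sel]
    r_case = r_case_all[sel]
    p = bootstrap_diff_pvalues(ctrl, case, sel, config)
    testable = np.isfinite(p)
    q = np.full(len(sel), np.nan)
    sig = np.zeros(len(sel), dtype=bool)
    if testable.any():
        q[testable], sig[testable] = bh_fdr(p[testable], config.fdr_q)
    labels = classify_gain_loss(
        r_ctrl, r_case, sig, high=config.selection_cutoff, low=config.low_threshold
    )

    rows = []
    for level in fdr_grid:
        sig_l = np.zeros(len(sel), dtype=bool)
        if testable.any():
            _, sig_l[testable] = bh_fdr(p[testable], level)
        lab_l = classify_gain_loss(
            r_ctrl, r_case, sig_l, high=config.selection_cutoff,
            low=config.low_threshold,
        )
        rows.append(
            {
                "fdr_q": level,
                "n_significant": int(sig_l.sum()),
                "n_gain": int((lab_l == LABEL_GAIN).sum()),
                "n_loss": int((lab_l == LABEL_LOSS).sum()),
            }
        )

    return DifferentialResult(
        gene_ids=ctrl.gene_ids[sel].copy(),
        r_ctrl=r_ctrl,
        r_case=r_case,
        delta=r_case - r_ctrl,
        p_boot=p,
        q_bh=q,
        label=labels,
        n_genes_tested=len(r_ctrl_all),
        fdr_grid_counts=pd.DataFrame(rows),
        config=config,
    )
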