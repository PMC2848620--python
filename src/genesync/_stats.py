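"""Vectorized correlation kernels shared by the inference modules.

Everything here operates on plain ndarrays. Degenerate rows (zero variance
in either region) yield NaN rather than raising, so callers can run fully
vectorized and count/exclude degenerates afterwards.
"""

from __future__ import annotations

import zlib

import numpy as np

# ~64 MB of float64 per intermediate tensor; keeps the batched bootstrap
# within a small, predictable memory envelope at any problem size.
_BLOCK_BUDGET = 8_000_000


def stream_key(parts) -> list[int]:
    """Deterministic seed sequence from a base seed plus string labels.

    CRC32 (not ``hash``) so streams are stable across processes and runs.
    """
    out = []
    for p in parts:
        out.append(int(p) if isinstance(p, (int, np.integer)) else zlib.crc32(p.encode()))
    return out


def rowwise_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson r between matching rows of two (G, n) matrices.

    Returns a length-G vector; rows where either side has zero variance map
    to NaN.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", Ac, Bc)
    den = np.sqrt(np.einsum("ij,ij->i", Ac, Ac) * np.einsum("ij,ij->i", Bc, Bc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, np.nan)
    return np.clip(r, -1.0, 1.0)


def resample_rvalues(
    A: np.ndarray,
    B: np.ndarray,
    idx: np.ndarray,
    ages: np.ndarray | None = None,
    detrend: bool = False,
) -> np.ndarray:
    """Genewise Pearson r for a batch of subject resamples.

    Parameters
    ----------
    A, B : ndarray, shape (G, n)
        Paired region matrices (columns are subjects, already aligned).
    idx : ndarray, shape (C, n)
        Subject indices per resample (with-replacement bootstrap draws or
        permutations).
    ages : ndarray, shape (n,), optional
        Subject ages; required when ``detrend`` is True.
    detrend : bool
        If True, OLS-residualize each gene on the *resample's own* ages in
        both regions before correlating (intercept included).

    Returns
    -------
    ndarray, shape (G, C) of r values, NaN where a resample is degenerate.
    """
    A3 = A[:, idx]  # (G, C, n)
    B3 = B[:, idx]
    A3 = A3 - A3.mean(axis=-1, keepdims=True)
    B3 = B3 - B3.mean(axis=-1, keepdims=True)
    if detrend:
        if ages is None:
            raise ValueError("ages required for detrended resampling")
        ag = np.asarray(ages, dtype=float)[idx]  # (C, n)
        agc = ag - ag.mean(axis=-1, keepdims=True)
        ss_age = np.einsum("cj,cj->c", agc, agc)  # (C,)
        safe = np.where(ss_age > 0, ss_age, 1.0)
        slope_a = np.einsum("gcj,cj->gc", A3, agc) / safe
        slope_b = np.einsum("gcj,cj->gc", B3, agc) / safe
        A3 = A3 - slope_a[..., None] * agc
        B3 = B3 - slope_b[..., None] * agc
    num = np.einsum("gcj,gcj->gc", A3, B3)
    den = np.sqrt(
        np.einsum("gcj,gcj->gc", A3, A3) * np.einsum("gcj,gcj->gc", B3, B3)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, np.nan)
    return np.clip(r, -1.0, 1.0)


def block_sizes(n_genes: int, n_resamples: int, n_subjects: int) -> tuple[int, int]:
    """(gene_block, resample_block) keeping each work tensor within budget."""
    g_block = max(1, min(n_genes, _BLOCK_BUDGET // max(1, n_resamples * 4)))
    c_block = max(1, min(n_resamples, _BLOCK_BUDGET // max(1, g_block * n_subjects)))
    return g_block, c_block


def random_derangement(rng: np.random.Generator, n: int) -> np.ndarray:
    """A uniformly random permutation of range(n) with no fixed point."""
    if n < 2:
        raise ValueError("derangement needs n >= 2")
    base = np.arange(n)
    while True:  # acceptance probability ~ 1/e, a handful of draws
        p = rng.permutation(n)
        if not np.any(p == base):
            return p


def canonical_subject_order(subject_ids: np.ndarray) -> np.ndarray:
    """Positions sorting subjects by id.

    Resampling in this canonical space makes every seeded routine invariant
    to the column order of the input matrices.
    """
    return np.argsort(np.asarray(subject_ids, dtype=str), kind="stable")
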