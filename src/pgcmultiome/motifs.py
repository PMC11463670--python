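"""PWM scanning, motif enrichment against matched backgrounds, and
per-cell motif activity (bias-corrected deviation z-scores).

PFMs become log-odds PWMs with a pseudocount split by background base
frequencies; scanning reports every window on either strand whose score
reaches a fraction of the motif's maximum achievable score (N bases score
0). Enrichment is an upper-tail hypergeometric against GC/accessibility-
matched background peaks. Per-cell activity follows the deviation-score
construction: observed motif-peak counts minus the depth-scaled
expectation, standardized against background iterations in which every
motif peak is replaced by a matched peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import hypergeom

from .core import PeakSet, ValidationError
from .differential import bh_adjust
from .links import _match_bins, sample_matched_background

BASE_ORDER = "ACGT"


@dataclass
class Pwm:
    motif_id: str
    name: str
    matrix: np.ndarray  # 4 x L log-odds
    max_score: float

    @property
    def length(self) -> int:
        return self.matrix.shape[1]


def pfm_to_pwm(
    pfm: np.ndarray,
    motif_id: str = "motif",
    name: str | None = None,
    pseudocount: float = 0.8,
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> Pwm:
    """Log-odds PWM: log2(((pfm + pc*bg) / (colsum + pc)) / bg)."""
    pfm = np.asarray(pfm, dtype=float)
    if pfm.ndim != 2 or pfm.shape[0] != 4:
        raise ValidationError("PFM must be 4 x L")
    if (pfm < 0).any():
        raise ValidationError("negative PFM entry")
    colsum = pfm.sum(axis=0)
    if (colsum == 0).any():
        raise ValidationError("PFM column with zero counts")
    bg = np.asarray(background, dtype=float)[:, None]
    probs = (pfm + pseudocount * bg) / (colsum + pseudocount)
    mat = np.log2(probs / bg)
    return Pwm(motif_id, name or motif_id, mat, float(mat.max(axis=0).sum()))


_RC_INDEX = np.array([3, 2, 1, 0])  # A<->T, C<->G


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)  # 4 = N
    for i, b in enumerate(BASE_ORDER):
        out[arr == ord(b)] = i
    return out


def scan_sequences(
    sequences: dict[str, str],
    pwm: Pwm,
    threshold_frac: float = 0.8,
) -> pd.DataFrame:
    """All windows on either strand scoring >= threshold_frac * max_score.

    The reverse strand scans the reverse complement; its hits are reported
    at the forward-strand offset of the window. N bases contribute 0.
    """
    L = pwm.length
    mat5 = np.concatenate([pwm.matrix, np.zeros((1, L))], axis=0)  # row 4: N
    rc = mat5[_RC_INDEX][:, ::-1]
    rc5 = np.concatenate([rc, np.zeros((1, L))], axis=0)
    cut = threshold_frac * pwm.max_score
    rows = []
    for name, seq in sequences.items():
        code = _encode(seq)
        n = len(code)
        if n < L:
            continue
        win = np.lib.stride_tricks.sliding_window_view(code, L)
        pos = np.arange(L)
        fwd = mat5[win, pos].sum(axis=1)
        rev = rc5[win, pos].sum(axis=1)
        for strand, scores in (("+", fwd), ("-", rev)):
            for off in np.flatnonzero(scores >= cut - 1e-12):
                rows.append(
                    {
                        "peak": name,
                        "motif_id": pwm.motif_id,
                        "offset": int(off),
                        "strand": strand,
                        "score": float(scores[off]),
                    }
                )
    return pd.DataFrame(
        rows, columns=["peak", "motif_id", "offset", "strand", "score"]
    )


def build_hit_matrix(
    sequences: dict[str, str],
    pwms: list[Pwm],
    peak_ids: list[str],
    threshold_frac: float = 0.8,
) -> tuple[sp.csr_matrix, pd.DataFrame]:
    """Binary peaks x motifs matrix plus the full per-hit table."""
    frames = [scan_sequences(sequences, pwm, threshold_frac) for pwm in pwms]
    hits = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["peak", "motif_id", "offset", "strand", "score"]
    )
    pi = {p: i for i, p in enumerate(peak_ids)}
    mi = {p.motif_id: j for j, p in enumerate(pwms)}
    M = sp.lil_matrix((len(peak_ids), len(pwms)), dtype=np.int8)
    for _, h in hits.iterrows():
        if h["peak"] in pi:
            M[pi[h["peak"]], mi[h["motif_id"]]] = 1
    return M.tocsr(), hits


def matched_background_peaks(
    foreground: np.ndarray,
    peaks: PeakSet,
    n: int,
    seed: int = 0,
) -> np.ndarray:
    """Background peaks sampled without replacement, stratified so the
    background's (GC decile, accessibility decile) histogram matches the
    foreground's; falls back to the nearest stratum when one runs short.
    Disjoint from the foreground."""
    foreground = np.asarray(foreground, dtype=int)
    n_peaks = len(peaks)
    if n > n_peaks - len(foreground):
        raise ValidationError("n exceeds available background candidates")
    gc = np.nan_to_num(peaks.gc_content, nan=0.5)
    gc_bins = _match_bins(gc)
    acc_bins = _match_bins(peaks.mean_accessibility)
    rng = np.random.default_rng(seed)
    fg_set = set(foreground.tolist())

    # per-stratum quota proportional to the foreground composition
    strata = gc_bins[foreground] * 10 + acc_bins[foreground]
    want = pd.Series(strata).value_counts()
    quota = (want / want.sum() * n).round().astype(int)
    # fix rounding drift
    drift = n - int(quota.sum())
    if drift != 0 and len(quota):
        quota.iloc[0] += drift
    all_strata = gc_bins * 10 + acc_bins
    chosen: list[int] = []
    for stratum, q in quota.items():
        pool = np.flatnonzero(all_strata == stratum)
        pool = pool[~np.isin(pool, list(fg_set) + chosen)]
        if len(pool) >= q:
            chosen.extend(rng.choice(pool, size=q, replace=False).tolist())
        else:
            chosen.extend(pool.tolist())
    if len(chosen) < n:  # nearest-stratum fallback
        rest = np.flatnonzero(~np.isin(np.arange(n_peaks), list(fg_set) + chosen))
        extra = rng.choice(rest, size=n - len(chosen), replace=False)
        chosen.extend(extra.tolist())
    return np.array(chosen[:n], dtype=int)


def motif_enrichment(
    foreground: np.ndarray,
    background: np.ndarray,
    hit_matrix: sp.spmatrix,
    motif_ids: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric motif enrichment over fg vs bg peaks.

    Universe = fg + bg; fold = fg hit rate / bg hit rate with a +0.5
    continuity guard on a zero bg rate; BH across motifs.
    """
    foreground = np.asarray(foreground, dtype=int)
    background = np.asarray(background, dtype=int)
    if foreground.size == 0:
        raise ValidationError("empty foreground")
    if np.intersect1d(foreground, background).size:
        raise ValidationError("foreground and background overlap")
    H = sp.csr_matrix(hit_matrix)
    fg_hits = np.asarray(H[foreground].sum(axis=0)).ravel()
    bg_hits = np.asarray(H[background].sum(axis=0)).ravel()
    n_fg, n_bg = len(foreground), len(background)
    N = n_fg + n_bg
    rows = []
    for j, mid in enumerate(motif_ids):
        K = int(fg_hits[j] + bg_hits[j])
        k = int(fg_hits[j])
        p = float(hypergeom.sf(k - 1, N, K, n_fg)) if K else 1.0
        fg_rate = k / n_fg
        bg_rate = bg_hits[j] / n_bg
        fold = fg_rate / bg_rate if bg_rate > 0 else (k + 0.5) / n_fg / ((bg_hits[j] + 0.5) / n_bg)
        rows.append(
            {
                "motif_id": mid,
                "fg_hits": k,
                "bg_hits": int(bg_hits[j]),
                "fold": fold,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    out["significant"] = out["p_value"] < alpha
    return out


@dataclass
class DeviationMatrix:
    raw: np.ndarray  # motifs x cells
    z: np.ndarray
    motif_ids: list[str]
    cell_ids: list[str]
    n_iterations: int


def chromvar_deviations(
    atac_counts: sp.spmatrix,
    hit_matrix: sp.spmatrix,
    peaks: PeakSet,
    motif_ids: list[str],
    cell_ids: list[str],
    n_iterations: int = 50,
    seed: int = 0,
) -> DeviationMatrix:
    """Bias-corrected per-cell motif deviations.

    With e_p = peak p's share of the grand total, the expected motif count
    for cell i is T_i * sum_{p in motif} e_p; the raw deviation is
    (observed - expected)/expected. Each background iteration replaces
    every motif peak with a GC/accessibility-matched sampled peak and
    recomputes; z standardizes the raw deviation against that null.
    Motifs whose expected count is zero are flagged missing (NaN).
    """
    C = sp.csr_matrix(atac_counts, dtype=float)
    H = sp.csr_matrix(hit_matrix, dtype=float)
    n_peaks, n_cells = C.shape
    if H.shape[0] != n_peaks:
        raise ValidationError("hit matrix and counts cover different peaks")
    T = np.asarray(C.sum(axis=0)).ravel()
    grand = T.sum()
    e = np.asarray(C.sum(axis=1)).ravel() / max(grand, 1e-300)

    def deviations(Hm: sp.spmatrix) -> np.ndarray:
        obs = np.asarray((Hm.T @ C).todense())
        expected = np.outer(np.asarray(Hm.T @ e).ravel(), T)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(expected > 0, (obs - expected) / expected, np.nan)

    raw = deviations(H)

    gc = np.nan_to_num(peaks.gc_content, nan=0.5)
    gc_bins = _match_bins(gc)
    acc_bins = _match_bins(np.asarray(C.mean(axis=1)).ravel())
    rng = np.random.default_rng(seed)

    bg = np.empty((n_iterations, len(motif_ids), n_cells))
    motif_peaks = [np.flatnonzero(np.asarray(H[:, j].todense()).ravel()) for j in range(len(motif_ids))]
    for it in range(n_iterations):
        Hb = sp.lil_matrix(H.shape, dtype=float)
        for j, mp in enumerate(motif_peaks):
            if len(mp) == 0:
                continue
            repl = _matched_replacement(mp, gc_bins, acc_bins, rng)
            Hb[repl, j] = 1.0
        bg[it] = deviations(Hb.tocsr())
    mu = bg.mean(axis=0)
    sd = bg.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (raw - mu) / np.maximum(sd, 1e-300), np.nan)
    return DeviationMatrix(raw, z, list(motif_ids), list(cell_ids), n_iterations)


def _matched_replacement(
    motif_peaks: np.ndarray,
    gc_bins: np.ndarray,
    acc_bins: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """For each motif peak, draw one peak from the same (GC, accessibility)
    stratum (with replacement across draws)."""
    strata = gc_bins * 10 + acc_bins
    out = np.empty(len(motif_peaks), dtype=int)
    for i, p in enumerate(motif_peaks):
        pool = np.flatnonzero(strata == strata[p])
        out[i] = pool[rng.integers(len(pool))]
    return np.unique(out)
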