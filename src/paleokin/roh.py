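"""Runs of homozygosity from diploid genotypes, and parental relatedness.

A two-state HMM over fixed genetic-map windows: in the non-autozygous state
the heterozygous-call count per window is Binomial(n, expected
heterozygosity); in the autozygous state the rate collapses to a small
residual (genotyping error).  Viterbi segments of the autozygous state are
reported in cM.  The summed length of long segments maps to the
relatedness class of the individual's parents through the expectation
E[sum ROH] = F * L, where F is the inbreeding coefficient (the parents'
kinship) and L the genetic map length: offspring of second cousins
(F = 1/64) on a 3545 cM map are expected to carry ~55 cM of autozygosity.

This genotype-level HMM is a deliberate simplification of reference-panel
haplotype-copying ROH callers; it requires genuinely diploid calls
(pseudohaploid data carry no heterozygote information) and refuses
ultra-sparse input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .synthetic import AlleleFrequencySet, TOTAL_MAP_CM

__all__ = [
    "ROHSegment",
    "ROHParams",
    "call_roh",
    "parental_degree_from_roh",
    "ROH_BANDS",
]


@dataclass
class ROHSegment:
    chrom: int
    start_cm: float
    end_cm: float
    posterior_autozygous: float = float("nan")

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm


@dataclass
class ROHParams:
    window_cm: float = 1.0
    residual_het: float = 0.002  # het-call rate inside true ROH
    mean_segment_cm: float = 15.0
    autozygous_prior: float = 0.02
    min_expected_het_per_window: float = 1.0

    def __post_init__(self):
        if self.window_cm < 0.5:
            raise ValueError("window size must be >= 0.5 cM")


def _viterbi2(log_emit: np.ndarray, log_pi: np.ndarray, log_trans: np.ndarray):
    n = log_emit.shape[0]
    back = np.zeros((n, 2), dtype=np.int8)
    v = log_pi + log_emit[0]
    for t in range(1, n):
        cand = v[:, None] + log_trans
        back[t] = np.argmax(cand, axis=0)
        v = cand[back[t], np.arange(2)] + log_emit[t]
    path = np.zeros(n, dtype=np.int8)
    path[-1] = int(np.argmax(v))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def _forward_backward2(log_emit, log_pi, log_trans):
    n = log_emit.shape[0]
    alpha = np.zeros((n, 2))
    alpha[0] = log_pi + log_emit[0]
    for t in range(1, n):
        x = alpha[t - 1][:, None] + log_trans
        m = x.max(axis=0)
        alpha[t] = log_emit[t] + m + np.log(np.exp(x - m).sum(axis=0))
    beta = np.zeros((n, 2))
    for t in range(n - 2, -1, -1):
        x = log_trans + (beta[t + 1] + log_emit[t + 1])[None, :]
        m = x.max(axis=1)
        beta[t] = m + np.log(np.exp(x - m[:, None]).sum(axis=1))
    post = alpha + beta
    post -= post.max(axis=1, keepdims=True)
    p = np.exp(post)
    return p / p.sum(axis=1, keepdims=True)


def call_roh(
    genotypes: np.ndarray,
    freqs: AlleleFrequencySet,
    params: ROHParams | None = None,
) -> list[ROHSegment]:
    """Call ROH segments for one individual.

    ``genotypes``: diploid vector {0,1,2} with -1 for missing, aligned to
    ``freqs``.  Raises ValueError when the data are too sparse for the
    window emission model (expected het calls per window < 1).
    """
    params = params or ROHParams()
    g = np.asarray(genotypes)
    segments: list[ROHSegment] = []
    log_pi = np.log(
        np.array([1 - params.autozygous_prior, params.autozygous_prior])
    )
    stay = np.exp(-params.window_cm / params.mean_segment_cm)
    enter = params.autozygous_prior * (1 - stay)
    trans = np.array([[1 - enter, enter], [1 - stay, stay]])
    log_trans = np.log(trans)

    exp_het_checked = False
    for ci in np.unique(freqs.chrom):
        m = freqs.chrom == ci
        pos = freqs.cm[m]
        gc = g[m]
        fc = freqs.freq[m]
        called = gc >= 0
        if called.sum() == 0:
            continue
        lo = pos.min()
        win = ((pos - lo) // params.window_cm).astype(int)
        n_win = win.max() + 1
        n_w = np.bincount(win[called], minlength=n_win)
        het_w = np.bincount(win[called & (gc == 1)], minlength=n_win)
        exp_het = np.bincount(
            win[called], weights=2 * fc[called] * (1 - fc[called]),
            minlength=n_win,
        )
        if not exp_het_checked:
            mean_expected = exp_het[n_w > 0].mean() if (n_w > 0).any() else 0.0
            if mean_expected < params.min_expected_het_per_window:
                raise ValueError(
                    "coverage too sparse for ROH calling: expected "
                    f"{mean_expected:.2f} heterozygous calls per "
                    f"{params.window_cm} cM window (< "
                    f"{params.min_expected_het_per_window}); use larger "
                    "windows or deeper data"
                )
            exp_het_checked = True
        use = n_w > 0
        rate_n = np.clip(exp_het[use] / np.maximum(n_w[use], 1), 1e-4, 0.6)
        log_emit = np.stack(
            [
                binom.logpmf(het_w[use], n_w[use], rate_n),
                binom.logpmf(het_w[use], n_w[use], params.residual_het),
            ],
            axis=1,
        )
        path = _viterbi2(log_emit, log_pi, log_trans)
        post = _forward_backward2(log_emit, log_pi, log_trans)
        win_ids = np.nonzero(use)[0]
        start = None
        for k, w in enumerate(win_ids):
            if path[k] == 1 and start is None:
                start = k
            if (path[k] == 0 or k == len(win_ids) - 1) and start is not None:
                end = k if path[k] == 0 else k + 1
                seg_w = win_ids[start:end]
                segments.append(
                    ROHSegment(
                        chrom=int(ci),
                        start_cm=lo + seg_w[0] * params.window_cm,
                        end_cm=lo + (seg_w[-1] + 1) * params.window_cm,
                        posterior_autozygous=float(post[start:end, 1].mean()),
                    )
                )
                start = None
    return segments


# sum-of-long-ROH bands (cM) -> parental relatedness class, centred on
# F*L expectations with geometric midpoint boundaries (L = 3545 cM):
# F = 1/128 (6th) -> 28; 1/64 (5th, second cousins) -> 55;
# 1/32 (4th) -> 111; 1/16 (3rd, first cousins) -> 222.
ROH_BANDS = [
    (10.0, "parents unrelated (> 3rd cousins)"),
    (35.0, "~6th degree"),
    (110.0, "~5th degree (second cousins)"),
    (220.0, "~4th degree"),
    (float("inf"), "<= 3rd degree"),
]


def parental_degree_from_roh(
    segments: list[ROHSegment],
    long_threshold: float = 20.0,
    boundary_tol: float = 5.0,
) -> dict:
    """Map an individual's summed long-ROH length to a parental class.

    Returns {'sum_long_roh', 'classification', 'boundary_flag'}; a sum
    within ``boundary_tol`` of a band boundary reports both neighbouring
    classes with a flag.
    """
    s = sum(seg.length_cm for seg in segments if seg.length_cm > long_threshold)
    labels = [lab for _, lab in ROH_BANDS]
    uppers = [u for u, _ in ROH_BANDS]
    k = next(i for i, u in enumerate(uppers) if s < u)
    cls = labels[k]
    flag = False
    for i, u in enumerate(uppers[:-1]):
        if abs(s - u) <= boundary_tol:
            cls = f"{labels[i]} / {labels[i + 1]} (boundary)"
            flag = True
            break
    return {"sum_long_roh": float(s), "classification": cls, "boundary_flag": flag}
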