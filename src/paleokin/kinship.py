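"""Pairwise relatedness from low-coverage pseudohaploid data.

Three estimators, fused into consensus degree calls:

* **Pairwise mismatch rate (PMR).**  The fraction of overlapping
  pseudohaploid sites at which two individuals carry different alleles.
  Normalized against an unrelated baseline b, its expectation is
  b * (1 - r/2) where r = k1/2 + k2 is the relatedness coefficient:
  1.0 for unrelated pairs, 0.875 for 2nd degree, 0.75 for 1st degree and
  0.5 for identical genomes.  Degrees are called with midpoint cutoffs
  between those expectations; standard errors come from a
  leave-one-window-out jackknife over genetic-map windows.

* **Maximum-likelihood IBD coefficients (k0, k1, k2)** from genotype
  likelihoods, maximizing the read-level likelihood over the k-simplex
  (coarse grid plus local zoom), in the spirit of genotype-likelihood
  relatedness estimators for degraded samples.

* **Sibling vs parent-offspring HMM.**  A windowed 3-state (IBD0/1/2) HMM
  over binomial mismatch counts: the parent-offspring model pins the whole
  genome in IBD1 while the sibling model mixes all three states, so the two
  hypotheses differ in the variance profile of windowed mismatch rates even
  when the genome-wide PMR is identical.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import binom

from .genotype_io import MISSING, GenotypePanel
from .synthetic import AlleleFrequencySet, ReadCounts

__all__ = [
    "PairEstimate",
    "pairwise_mismatch_rate",
    "normalize_pmr",
    "classify_degree",
    "genotype_likelihoods",
    "ml_k_coefficients",
    "first_degree_type_hmm",
    "consensus_degrees",
    "ConsensusCall",
    "expected_pmr_baseline",
    "DEGREE_CUTOFFS",
]

# Midpoints between expected normalized PMR values 0.5 / 0.75 / 0.875 /
# 0.9375 / 1.0 (identical, 1st, 2nd, 3rd, unrelated).
DEGREE_CUTOFFS = {
    "identical": 0.625,
    "1st": 0.8125,
    "2nd": 0.90625,
    "3rd": 0.953125,
}

R_CUTOFFS = {  # midpoints (geometric) on r = k1/2 + k2
    "identical": 1 / math.sqrt(2),
    "1st": 0.5 / math.sqrt(2),
    "2nd": 0.25 / math.sqrt(2),
    "3rd": 0.125 / math.sqrt(2),
}


@dataclass
class PairEstimate:
    pair: tuple[str, str]
    n_overlap: int = 0
    pmr: float = float("nan")
    pmr_se: float = float("nan")
    normalized_pmr: float = float("nan")
    normalized_se: float = float("nan")
    k0: float = float("nan")
    k1: float = float("nan")
    k2: float = float("nan")
    r: float = float("nan")
    r_over_k0: float = float("nan")
    degree_call: str = "undetermined"
    first_degree_type: str = "NA"
    loglik_margin: float = float("nan")


def _window_index(panel: GenotypePanel, window_cm: float) -> np.ndarray:
    """Assign each SNP to a genome-wide (chromosome, window) bin index."""
    snp = panel.snp
    chroms = np.asarray(snp.chrom)
    win = np.zeros(len(snp), dtype=np.int64)
    offset = 0
    for c in pd_unique(chroms):
        m = chroms == c
        w = (snp.cm[m] // window_cm).astype(np.int64)
        # renumber to consecutive
        _, w = np.unique(w, return_inverse=True)
        win[m] = w + offset
        offset += w.max() + 1 if len(w) else 0
    return win


def pd_unique(arr):
    seen, out = set(), []
    for x in arr:
        if x not in seen:
            seen.add(x)
            out.append(x)
    return out


def pairwise_mismatch_rate(
    panel: GenotypePanel,
    i: str,
    j: str,
    window_cm: float = 10.0,
) -> tuple[float, int, float]:
    """PMR, overlap count, and jackknife SE for one pair.

    The SE is a leave-one-window-out block jackknife over ``window_cm``
    genetic-map windows, robust to linkage between nearby SNPs.
    """
    gi = panel.genotypes[panel.index_of(i)]
    gj = panel.genotypes[panel.index_of(j)]
    shared = (gi != MISSING) & (gj != MISSING)
    n = int(shared.sum())
    if n == 0:
        return (float("nan"), 0, float("nan"))
    mismatch = shared & (gi != gj)
    pmr = float(mismatch.sum()) / n
    win = _window_index(panel, window_cm)
    n_w = np.bincount(win[shared])
    m_w = np.bincount(win[shared & mismatch], minlength=len(n_w))
    use = n_w > 0
    n_w, m_w = n_w[use], m_w[use]
    W = len(n_w)
    if W < 2:
        return (pmr, n, float("nan"))
    tot_n, tot_m = n_w.sum(), m_w.sum()
    loo = (tot_m - m_w) / (tot_n - n_w)
    se = math.sqrt((W - 1) / W * float(np.sum((loo - loo.mean()) ** 2)))
    return (pmr, n, se)


def expected_pmr_baseline(freqs: AlleleFrequencySet) -> float:
    """Expected pseudohaploid mismatch rate between unrelated individuals."""
    p = freqs.freq
    return float(np.mean(2 * p * (1 - p)))


def all_pair_pmr(
    panel: GenotypePanel, window_cm: float = 10.0
) -> list[PairEstimate]:
    out = []
    for a, b in itertools.combinations(panel.ids, 2):
        pmr, n, se = pairwise_mismatch_rate(panel, a, b, window_cm)
        out.append(PairEstimate(pair=(a, b), n_overlap=n, pmr=pmr, pmr_se=se))
    return out


def normalize_pmr(
    all_pairs: list[PairEstimate],
    method: str = "median-of-unrelated",
    baseline: Optional[float] = None,
    unrelated_ids: Optional[set] = None,
) -> list[PairEstimate]:
    """Normalize each pair's PMR by the unrelated baseline.

    ``median-of-unrelated`` takes the median PMR over pairs presumed
    unrelated (restricted to ``unrelated_ids`` when given, else all pairs,
    the usual assumption that most pairs in a panel are unrelated);
    ``explicit-baseline`` divides by a supplied constant.
    """
    if method == "explicit-baseline":
        if baseline is None:
            raise ValueError("explicit-baseline requires a baseline value")
        b = baseline
    elif method == "median-of-unrelated":
        vals = [
            p.pmr
            for p in all_pairs
            if not math.isnan(p.pmr)
            and (
                unrelated_ids is None
                or (p.pair[0] in unrelated_ids and p.pair[1] in unrelated_ids)
            )
        ]
        if not vals:
            raise ValueError("no usable baseline pairs and no explicit baseline")
        b = float(np.median(vals))
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    out = []
    for p in all_pairs:
        q = PairEstimate(**vars(p))
        q.normalized_pmr = p.pmr / b
        q.normalized_se = p.pmr_se / b if not math.isnan(p.pmr_se) else float("nan")
        out.append(q)
    return out


def classify_degree(pair: PairEstimate, min_overlap: int = 2000) -> str:
    """Degree call from the normalized PMR with midpoint cutoffs.

    Undetermined when the overlap is below ``min_overlap`` or when the
    +-2 SE interval spans a cutoff (the call would not be robust).
    """
    x = pair.normalized_pmr
    if math.isnan(x) or pair.n_overlap < min_overlap:
        return "undetermined"
    se = pair.normalized_se
    if not math.isnan(se):
        for cut in DEGREE_CUTOFFS.values():
            if x - 2 * se < cut < x + 2 * se:
                return "undetermined"
    if x < DEGREE_CUTOFFS["identical"]:
        return "identical"
    if x < DEGREE_CUTOFFS["1st"]:
        return "1st"
    if x < DEGREE_CUTOFFS["2nd"]:
        return "2nd"
    if x < DEGREE_CUTOFFS["3rd"]:
        return "3rd"
    return "unrelated"


# ---------------------------------------------------------------------
# genotype likelihoods and ML k-coefficients
# ---------------------------------------------------------------------

def genotype_likelihoods(
    reads: ReadCounts, error: float = 0.01
) -> np.ndarray:
    """Binomial read-sampling likelihoods for genotypes {0, 1, 2}.

    Returns an array (n_ind, n_snps, 3); rows with zero depth get uniform
    likelihoods (no information).
    """
    if not 0.0 < error < 0.5:
        raise ValueError("error must be in (0, 0.5)")
    d = reads.depth
    a = reads.alt
    p_geno = np.array([error, 0.5, 1.0 - error])
    gl = np.stack(
        [binom.pmf(a, d, p) for p in p_geno], axis=-1
    )
    gl[d == 0] = 1.0 / 3.0
    return gl


def _pair_tables(freq: np.ndarray) -> np.ndarray:
    """P(g_i, g_j | IBD state, f) tables, shape (3 states, n, 3, 3)."""
    p = freq
    q = 1 - p
    hw = np.stack([q * q, 2 * p * q, p * p], axis=-1)  # (n, 3)
    n = len(p)
    t = np.zeros((3, n, 3, 3))
    t[0] = hw[:, :, None] * hw[:, None, :]
    # IBD1: shared allele s ~ freq; each genotype = s + independent allele
    for s, ps in ((0, q), (1, p)):
        cond = np.zeros((n, 3))
        for extra, pe in ((0, q), (1, p)):
            cond[:, s + extra] += pe
        t[1] += ps[:, None, None] * cond[:, :, None] * cond[:, None, :]
    idx = np.arange(3)
    t[2][:, idx, idx] = hw
    return t


def ml_k_coefficients(
    gl_i: np.ndarray,
    gl_j: np.ndarray,
    freqs: AlleleFrequencySet,
    informative: Optional[np.ndarray] = None,
    min_sites: int = 200,
    max_sites: int = 60_000,
    grid_step: float = 0.05,
) -> dict:
    """Maximum-likelihood (k0, k1, k2) on the simplex for one pair.

    Maximizes sum_s log sum_{gi,gj} GL_i(gi) GL_j(gj) P(gi,gj | k, f) by a
    coarse simplex grid followed by two local zoom refinements; ties break
    toward larger k0 (the conservative, less-related solution).
    Returns a dict with k0,k1,k2,r,r_over_k0,loglik,n_sites, or degree
    'undetermined' marker when fewer than ``min_sites`` informative sites.
    """
    if informative is None:
        informative = (gl_i.max(axis=1) - gl_i.min(axis=1) > 0) & (
            gl_j.max(axis=1) - gl_j.min(axis=1) > 0
        )
    idx = np.where(informative)[0]
    if len(idx) < min_sites:
        return {"undetermined": True, "n_sites": int(len(idx))}
    if len(idx) > max_sites:
        idx = idx[:: max(len(idx) // max_sites, 1)][:max_sites]
    f = freqs.freq[idx]
    tables = _pair_tables(f)  # (3, n, 3, 3)
    gi = gl_i[idx]
    gj = gl_j[idx]
    # A[s, state] = sum_{gi,gj} GL_i GL_j T_state
    outer = gi[:, :, None] * gj[:, None, :]
    A = np.stack(
        [np.einsum("nij,nij->n", outer, tables[s]) for s in range(3)], axis=1
    )
    A = np.maximum(A, 1e-300)

    def loglik(k):
        return float(np.log(A @ k).sum())

    def grid_points(center, step, span):
        pts = []
        k0s = np.arange(
            max(0.0, center[0] - span), min(1.0, center[0] + span) + 1e-9, step
        )
        k2s = np.arange(
            max(0.0, center[2] - span), min(1.0, center[2] + span) + 1e-9, step
        )
        for k0 in k0s:
            for k2 in k2s:
                k1 = 1.0 - k0 - k2
                if k1 < -1e-12:
                    continue
                pts.append(np.array([k0, max(k1, 0.0), k2]))
        return pts

    best, best_ll = None, -np.inf
    for k in grid_points((0.5, 0.0, 0.5), grid_step, 1.0):
        ll = loglik(k)
        if ll > best_ll + 1e-9 or (abs(ll - best_ll) <= 1e-9 and (best is None or k[0] > best[0])):
            best, best_ll = k, ll
    for step, span in ((grid_step / 5, grid_step), (grid_step / 25, grid_step / 5)):
        for k in grid_points(best, step, span):
            ll = loglik(k)
            if ll > best_ll + 1e-9 or (abs(ll - best_ll) <= 1e-9 and k[0] > best[0]):
                best, best_ll = k, ll
    k0, k1, k2 = (float(x) for x in best)
    r = k1 / 2 + k2
    return {
        "k0": k0,
        "k1": k1,
        "k2": k2,
        "r": r,
        "r_over_k0": r / k0 if k0 > 0 else float("inf"),
        "loglik": best_ll,
        "loglik_unrelated": loglik(np.array([1.0, 0.0, 0.0])),
        "n_sites": int(len(idx)),
        "site_lik": A,
    }


def degree_from_r(r: float) -> str:
    if r > R_CUTOFFS["identical"]:
        return "identical"
    if r > R_CUTOFFS["1st"]:
        return "1st"
    if r > R_CUTOFFS["2nd"]:
        return "2nd"
    if r > R_CUTOFFS["3rd"]:
        return "3rd"
    return "unrelated"


# canonical IBD-coefficient profiles per relatedness class
DEGREE_HYPOTHESES = {
    "identical": [(0.0, 0.0, 1.0)],
    "1st": [(0.0, 1.0, 0.0), (0.25, 0.5, 0.25)],  # parent-offspring, sibs
    "2nd": [(0.5, 0.5, 0.0)],
    "3rd": [(0.75, 0.25, 0.0)],
    "unrelated": [(1.0, 0.0, 0.0)],
}


def ml_degree_call(
    site_lik: np.ndarray, margin_threshold: float = 2.0
) -> tuple[str, float]:
    """Degree call by comparing canonical IBD-profile likelihoods.

    ``site_lik`` is the per-site per-IBD-state likelihood array A (n, 3)
    from the ML machinery; the call is the hypothesis class with the
    highest summed log-likelihood.  When the margin over the best
    competing class falls below ``margin_threshold`` log units the call is
    'undetermined' -- the data cannot separate neighbouring degrees (the
    analogue of the +-2 SE rule for the normalized PMR).
    """
    best_by_class = {}
    for cls, profiles in DEGREE_HYPOTHESES.items():
        best_by_class[cls] = max(
            float(np.log(np.maximum(site_lik @ np.array(k), 1e-300)).sum())
            for k in profiles
        )
    ranked = sorted(best_by_class.items(), key=lambda kv: -kv[1])
    (top_cls, top_ll), (_, second_ll) = ranked[0], ranked[1]
    margin = top_ll - second_ll
    if margin < margin_threshold:
        return ("undetermined", margin)
    return (top_cls, margin)


# ---------------------------------------------------------------------
# sibling vs parent-offspring HMM
# ---------------------------------------------------------------------

def _window_mismatch_counts(
    panel: GenotypePanel, i: str, j: str, window_cm: float
):
    gi = panel.genotypes[panel.index_of(i)]
    gj = panel.genotypes[panel.index_of(j)]
    shared = (gi != MISSING) & (gj != MISSING)
    mism = shared & (gi != gj)
    win = _window_index(panel, window_cm)
    n_w = np.bincount(win[shared])
    m_w = np.bincount(win[mism], minlength=len(n_w))
    use = n_w > 0
    return n_w[use], m_w[use]


def first_degree_type_hmm(
    panel: GenotypePanel,
    i: str,
    j: str,
    baseline_pmr: float,
    window_cm: float = 20.0,
    min_windows: int = 20,
    ibd_segment_cm: float = 25.0,
) -> tuple[str, float]:
    """Distinguish sibling from parent-offspring for a 1st-degree pair.

    Sibling model: 3-state IBD HMM with stationary weights (1/4, 1/2, 1/4)
    and window-to-window mixing exp(-window/segment length); emissions are
    Binomial(n_w, rate) with rates (b, 0.75 b, 0.5 b) for IBD0/1/2.
    Parent-offspring model: the genome is entirely IBD1 (rate 0.75 b).
    Returns (winning model, log-likelihood margin); ('NA', nan) with fewer
    than ``min_windows`` usable windows.
    """
    n_w, m_w = _window_mismatch_counts(panel, i, j, window_cm)
    if len(n_w) < min_windows:
        return ("NA", float("nan"))
    b = baseline_pmr
    rates = np.array([b, 0.75 * b, 0.5 * b])
    log_emit = binom.logpmf(m_w[:, None], n_w[:, None], rates[None, :])
    # parent-offspring: all windows IBD1
    ll_po = float(log_emit[:, 1].sum())
    # sibling: forward algorithm
    pi = np.array([0.25, 0.5, 0.25])
    a = math.exp(-window_cm / ibd_segment_cm)
    trans = a * np.eye(3) + (1 - a) * pi[None, :]
    log_trans = np.log(trans)
    alpha = np.log(pi) + log_emit[0]
    for t in range(1, len(n_w)):
        alpha = log_emit[t] + _logsumexp_mat(alpha, log_trans)
    ll_sib = float(_logsumexp(alpha))
    margin = ll_sib - ll_po
    if margin >= 0:
        return ("sibling", margin)
    return ("parent-offspring", -margin)


def _logsumexp(x):
    m = np.max(x)
    return m + math.log(np.exp(x - m).sum())


def _logsumexp_mat(alpha, log_trans):
    # returns vector over next states
    x = alpha[:, None] + log_trans
    m = x.max(axis=0)
    return m + np.log(np.exp(x - m).sum(axis=0))


# ---------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------

@dataclass
class ConsensusCall:
    pair: tuple[str, str]
    call: str
    conflict: bool
    confidence: float
    methods: dict[str, str] = field(default_factory=dict)
    first_degree_type: str = "NA"
    type_margin: float = float("nan")


def consensus_degrees(
    estimates_by_method: dict[str, dict[frozenset, tuple[str, float]]],
    first_degree_types: Optional[dict[frozenset, tuple[str, float]]] = None,
) -> dict[frozenset, ConsensusCall]:
    """Fuse per-method degree calls into consensus calls.

    ``estimates_by_method`` maps method name -> {pair -> (call, confidence)}.
    Undetermined calls abstain.  The consensus is the confidence-weighted
    majority; disagreement between determined calls raises a conflict flag
    (both calls retained in ``methods``), never a silent resolution.
    """
    pairs = set()
    for calls in estimates_by_method.values():
        pairs |= set(calls)
    out = {}
    for pr in pairs:
        votes: dict[str, float] = {}
        methods = {}
        for method, calls in estimates_by_method.items():
            if pr not in calls:
                continue
            call, conf = calls[pr]
            methods[method] = call
            if call == "undetermined":
                continue
            votes[call] = votes.get(call, 0.0) + conf
        if not votes:
            winner, conf, conflict = "undetermined", 0.0, False
        else:
            winner = max(votes, key=lambda c: votes[c])
            conf = votes[winner]
            conflict = len(votes) > 1
        a, b = sorted(pr)
        cc = ConsensusCall(
            pair=(a, b), call=winner, conflict=conflict,
            confidence=conf, methods=methods,
        )
        if first_degree_types and pr in first_degree_types and winner == "1st":
            cc.first_degree_type, cc.type_margin = first_degree_types[pr]
        out[pr] = cc
    return out
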