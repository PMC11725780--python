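"""Chromosomal sex from sequencing read counts, and matriline consistency.

Sex is called twice: from the Y read fraction Ry = nY / (nX + nY) with the
published thresholds (XX when the 95% CI lies below 0.016, XY when above
0.075), and from the X-to-autosome normalized coverage Rx (XX near 1,
XY near 0.5).  Both are reported; a conflict yields 'undetermined'.
Mitochondrial lineage labels, supplied per individual, are checked for
consistency along every maternal path of a pedigree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import math

import numpy as np
from scipy.stats import t as t_dist

from .pedigree import Pedigree

__all__ = ["SexCall", "ry_sex", "rx_sex", "combined_sex", "maternal_consistency"]

RY_XX_MAX = 0.016
RY_XY_MIN = 0.075
RX_XX_BAND = (0.8, 1.2)
RX_XY_BAND = (0.3, 0.7)


@dataclass
class SexCall:
    ry: float = float("nan")
    ry_ci: tuple[float, float] = (float("nan"), float("nan"))
    rx: float = float("nan")
    rx_ci: tuple[float, float] = (float("nan"), float("nan"))
    call: str = "undetermined"  # 'XX' | 'XY' | 'undetermined'


def ry_sex(n_y: int, n_x: int) -> SexCall:
    """Sex call from Y vs X+Y read counts.

    Each threshold is tested one-sidedly at 5% with the binomial normal
    approximation (the convention of the standard Ry typing script): XX when
    the upper bound sits below 0.016, XY when the lower bound clears 0.075.
    """
    total = n_x + n_y
    if total <= 0:
        return SexCall(call="undetermined")
    ry = n_y / total
    se = math.sqrt(max(ry * (1.0 - ry), 1.0 / total) / total)
    lo, hi = ry - 1.6449 * se, ry + 1.6449 * se
    if hi < RY_XX_MAX:
        call = "XX"
    elif lo > RY_XY_MIN:
        call = "XY"
    else:
        call = "undetermined"
    return SexCall(ry=ry, ry_ci=(lo, hi), call=call)


def rx_sex(
    x_coverage: Optional[float], autosome_coverages: dict[str, float] | list[float]
) -> SexCall:
    """Sex call from X coverage normalized by each autosome's coverage.

    The Rx statistic is the mean of X/autosome coverage ratios with a 95%
    t-interval over autosomes; XX requires the CI inside [0.8, 1.2], XY
    inside [0.3, 0.7].
    """
    cov = (
        list(autosome_coverages.values())
        if isinstance(autosome_coverages, dict)
        else list(autosome_coverages)
    )
    cov = [c for c in cov if c > 0]
    if x_coverage is None or len(cov) < 2:
        return SexCall(call="undetermined")
    ratios = np.array([x_coverage / c for c in cov])
    rx = float(ratios.mean())
    se = float(ratios.std(ddof=1) / np.sqrt(len(ratios)))
    half = t_dist.ppf(0.975, len(ratios) - 1) * se
    lo, hi = rx - half, rx + half
    if RX_XX_BAND[0] <= lo and hi <= RX_XX_BAND[1]:
        call = "XX"
    elif RX_XY_BAND[0] <= lo and hi <= RX_XY_BAND[1]:
        call = "XY"
    else:
        call = "undetermined"
    return SexCall(rx=rx, rx_ci=(lo, hi), call=call)


def combined_sex(ry_call: SexCall, rx_call: SexCall) -> SexCall:
    """Fuse the Ry and Rx calls; any disagreement -> undetermined."""
    calls = {ry_call.call, rx_call.call} - {"undetermined"}
    call = calls.pop() if len(calls) == 1 else "undetermined"
    return SexCall(
        ry=ry_call.ry, ry_ci=ry_call.ry_ci,
        rx=rx_call.rx, rx_ci=rx_call.rx_ci, call=call,
    )


def maternal_consistency(
    lineages: dict[str, str], pedigree: Pedigree
) -> list[tuple[str, str]]:
    """Mitochondrial-lineage violations along maternal paths.

    Returns pairs of individuals that share a matriline (are connected by
    mother edges) yet carry different lineage labels; empty means every
    maternal path connects identical labels.
    """
    by_root: dict[str, list[str]] = {}
    for iid in lineages:
        if iid not in pedigree:
            continue
        by_root.setdefault(pedigree.matriline_root(iid), []).append(iid)
    violations = []
    for members in by_root.values():
        labs = {i: lineages[i] for i in members}
        distinct = sorted(set(labs.values()))
        if len(distinct) > 1:
            ordered = sorted(members)
            for a_i in range(len(ordered)):
                for b_i in range(a_i + 1, len(ordered)):
                    a, b = ordered[a_i], ordered[b_i]
                    if labs[a] != labs[b]:
                        violations.append((a, b))
    return violations
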