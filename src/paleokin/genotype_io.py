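"""EIGENSTRAT-dialect genotype panels.

Genotype matrices are stored in memory as ``int8`` arrays of shape
(n_individuals, n_snps) holding counts of the alternate allele {0, 1, 2}
with ``-1`` as the missing sentinel; on disk the EIGENSTRAT convention of a
'9' character encodes missingness.  Pseudohaploid panels (one random read
per site) carry only {0, 2, -1}.  Genetic positions are kept in cM in
memory and written in Morgans, per the EIGENSTRAT convention; physical
positions are 1-based.  ``.gz``-compressed files are read transparently.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SNPPanel",
    "GenotypePanel",
    "FormatError",
    "read_eigenstrat",
    "write_eigenstrat",
    "intersect_panels",
]

MISSING = -1  # in-memory sentinel; 9 on disk

_VALID_ALLELES = set("ACGT")


class FormatError(ValueError):
    pass


@dataclass
class SNPPanel:
    ids: np.ndarray  # str
    chrom: np.ndarray  # str labels ('1'..'22', 'X', ...)
    cm: np.ndarray  # genetic position, cM
    bp: np.ndarray  # physical position, 1-based
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.cm = np.asarray(self.cm, dtype=float)
        self.bp = np.asarray(self.bp, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        if len(set(self.ids)) != len(self.ids):
            raise FormatError("SNP ids must be unique")
        for arr in (self.ref, self.alt):
            bad = [a for a in arr if a not in _VALID_ALLELES]
            if bad:
                raise FormatError(f"invalid allele(s): {sorted(set(bad))[:5]}")
        if np.any(self.bp <= 0):
            raise FormatError("physical positions must be positive (1-based)")

    def __len__(self):
        return len(self.ids)

    def take(self, idx) -> "SNPPanel":
        return SNPPanel(
            self.ids[idx], self.chrom[idx], self.cm[idx], self.bp[idx],
            self.ref[idx], self.alt[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids, "chrom": self.chrom, "cm": self.cm,
                "bp": self.bp, "ref": self.ref, "alt": self.alt,
            }
        )


@dataclass
class GenotypePanel:
    snp: SNPPanel
    genotypes: np.ndarray  # (n_ind, n_snp) int8; -1 missing
    ids: list[str]
    sexes: Optional[list[str]] = None
    pseudohaploid: bool = False

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n_ind, n_snp = self.genotypes.shape
        if n_snp != len(self.snp):
            raise FormatError(
                f"genotype matrix has {n_snp} SNPs but panel has {len(self.snp)}"
            )
        if n_ind != len(self.ids):
            raise FormatError("genotype matrix / individual id length mismatch")
        vals = set(np.unique(self.genotypes).tolist())
        if not vals <= {-1, 0, 1, 2}:
            raise FormatError(f"invalid genotype values {vals - {-1, 0, 1, 2}}")
        if self.pseudohaploid and 1 in vals:
            raise FormatError("pseudohaploid panel contains heterozygous calls")

    @property
    def n_individuals(self):
        return len(self.ids)

    @property
    def n_snps(self):
        return len(self.snp)

    def index_of(self, iid: str) -> int:
        return self.ids.index(iid)

    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING


def _open_maybe_gz(path: str, mode: str = "rt"):
    if os.path.exists(path):
        return open(path, mode)
    if os.path.exists(path + ".gz"):
        return gzip.open(path + ".gz", mode)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    raise FileNotFoundError(path)


def read_eigenstrat(prefix: str) -> tuple[SNPPanel, GenotypePanel]:
    """Read a .geno/.snp/.ind triplet (gzip accepted transparently)."""
    with _open_maybe_gz(prefix + ".snp") as fh:
        rows = [line.split() for line in fh if line.strip()]
    if not rows:
        raise FormatError(f"{prefix}.snp is empty")
    snp = SNPPanel(
        ids=[r[0] for r in rows],
        chrom=[r[1] for r in rows],
        cm=[float(r[2]) * 100.0 for r in rows],  # Morgans on disk -> cM
        bp=[int(r[3]) for r in rows],
        ref=[r[4] for r in rows],
        alt=[r[5] for r in rows],
    )
    with _open_maybe_gz(prefix + ".ind") as fh:
        ind_rows = [line.split() for line in fh if line.strip()]
    ids = [r[0] for r in ind_rows]
    sexes = [r[1] if len(r) > 1 else "U" for r in ind_rows]

    geno = np.empty((len(snp), len(ids)), dtype=np.int8)
    with _open_maybe_gz(prefix + ".geno") as fh:
        n = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if n >= len(snp):
                raise FormatError(
                    f"{prefix}.geno has more rows than {prefix}.snp"
                )
            if len(line) != len(ids):
                raise FormatError(
                    f"{prefix}.geno line {lineno}: row length {len(line)} != "
                    f"{len(ids)} individuals"
                )
            bad = set(line) - set("0129")
            if bad:
                raise FormatError(
                    f"{prefix}.geno line {lineno}: unknown character(s) {bad}"
                )
            geno[n] = np.frombuffer(line.encode(), dtype=np.uint8) - ord("0")
            n += 1
    if n != len(snp):
        raise FormatError(f"{prefix}.geno has {n} rows, expected {len(snp)}")
    geno = geno.T.copy()
    geno[geno == 9] = MISSING
    pseudo = not np.any(geno == 1)
    panel = GenotypePanel(snp, geno, ids, sexes, pseudohaploid=pseudo)
    return snp, panel


def write_eigenstrat(prefix: str, panel: GenotypePanel) -> None:
    snp = panel.snp
    with open(prefix + ".snp", "w") as fh:
        for i in range(len(snp)):
            fh.write(
                f"{snp.ids[i]}\t{snp.chrom[i]}\t{snp.cm[i] / 100.0:.8f}\t"
                f"{snp.bp[i]}\t{snp.ref[i]}\t{snp.alt[i]}\n"
            )
    with open(prefix + ".ind", "w") as fh:
        sexes = panel.sexes or ["U"] * panel.n_individuals
        for iid, sex in zip(panel.ids, sexes):
            fh.write(f"{iid}\t{sex}\tCase\n")
    geno = panel.genotypes.T.astype(np.int16)
    geno[geno == MISSING] = 9
    chars = geno.astype(np.uint8) + ord("0")
    with open(prefix + ".geno", "wb") as fh:
        for row in chars:
            fh.write(row.tobytes() + b"\n")


def intersect_panels(
    a: GenotypePanel, b: GenotypePanel
) -> tuple[GenotypePanel, GenotypePanel, int]:
    """Restrict two panels to SNPs non-missing in both.

    Panels are joined by SNP id; returns the two restricted panels and the
    overlap count.  An empty intersection is returned (with count 0), not
    raised.
    """
    ids_a = {sid: i for i, sid in enumerate(a.snp.ids)}
    shared = [(ids_a[sid], j) for j, sid in enumerate(b.snp.ids) if sid in ids_a]
    if not shared:
        import warnings

        warnings.warn("panels share no SNP ids", stacklevel=2)
        idx_a = np.array([], dtype=int)
        idx_b = np.array([], dtype=int)
    else:
        idx_a = np.array([i for i, _ in shared])
        idx_b = np.array([j for _, j in shared])
    ok = np.ones(len(idx_a), dtype=bool)
    if len(idx_a):
        ok = ~np.any(a.genotypes[:, idx_a] == MISSING, axis=0)
        ok &= ~np.any(b.genotypes[:, idx_b] == MISSING, axis=0)
    idx_a, idx_b = idx_a[ok], idx_b[ok]
    if len(idx_a) == 0:
        import warnings

        warnings.warn("SNP intersection after missingness filter is empty",
                      stacklevel=2)
    pa = GenotypePanel(
        a.snp.take(idx_a), a.genotypes[:, idx_a], a.ids, a.sexes, a.pseudohaploid
    )
    pb = GenotypePanel(
        b.snp.take(idx_b), b.genotypes[:, idx_b], b.ids, b.sexes, b.pseudohaploid
    )
    return pa, pb, int(len(idx_a))
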