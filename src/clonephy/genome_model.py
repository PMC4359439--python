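"""Data model and I/O for simple somatic mutations (SSMs) and subclonal CNVs.

An SSM is characterized by per-sample reference read counts ``a`` and total
read counts ``d`` at its locus, together with the probabilities ``mu_r`` /
``mu_v`` of sampling a reference-allele read from the reference / variant
cell population.  A subclonal CNV call carries a genomic interval, a total
copy number ``C`` with optional maternal/paternal breakdown ``Cm``/``Cp``,
and a per-sample population frequency ``phi``.

CNVs enter the phylogeny as *pseudo-SSMs*: synthetic heterozygous binary
mutations whose variant-read fraction encodes phi/2, so a CNV can be placed
on the clone tree exactly like a point mutation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "SSM",
    "CNV",
    "PseudoSSM",
    "Locus",
    "InputError",
    "load_ssm_table",
    "load_cnv_table",
    "write_ssm_table",
    "write_cnv_table",
    "cnv_to_pseudo_ssm",
    "default_support_depth",
    "associate_ssms_to_cnvs",
]

MATERNAL = "maternal"
PATERNAL = "paternal"
UNKNOWN = "unknown"

DEFAULT_EPSILON = 0.001


class InputError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass(frozen=True)
class Locus:
    """Genomic position, 0-based."""

    chrom: str
    pos: int


@dataclass
class SSM:
    """A simple somatic mutation with per-sample read counts.

    Parameters
    ----------
    id : str
        Unique mutation identifier.
    a : array of int
        Reference read counts, one per sample.
    d : array of int
        Total read counts, one per sample; ``b = d - a`` are variant reads.
    mu_r : float
        Probability of sampling a reference allele from the reference
        population (``1 - epsilon`` for a diploid locus).
    mu_v : float
        Probability of sampling a reference allele from the variant
        population absent CNVs; 0.5 for a heterozygous mutation.
    locus : Locus, optional
        Genomic position; required to associate the SSM with CNVs.
    phase : str
        'maternal', 'paternal' or 'unknown'.
    epsilon : float
        Per-mutation sequencing error probability.
    """

    id: str
    a: np.ndarray
    d: np.ndarray
    mu_r: float = 1.0 - DEFAULT_EPSILON
    mu_v: float = 0.5
    locus: Optional[Locus] = None
    phase: str = UNKNOWN
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.int64)
        self.d = np.asarray(self.d, dtype=np.int64)
        if self.a.shape != self.d.shape or self.a.ndim != 1:
            raise InputError(f"SSM {self.id}: a and d must be 1-D and equal length")
        if np.any(self.a < 0) or np.any(self.a > self.d):
            raise InputError(f"SSM {self.id}: a exceeds d or is negative")
        for name, val in (("mu_r", self.mu_r), ("mu_v", self.mu_v), ("epsilon", self.epsilon)):
            if not 0.0 <= val <= 1.0:
                raise InputError(f"SSM {self.id}: {name}={val} outside [0, 1]")
        if self.phase not in (MATERNAL, PATERNAL, UNKNOWN):
            raise InputError(f"SSM {self.id}: unknown phase {self.phase!r}")

    @property
    def n_samples(self) -> int:
        return len(self.d)

    @property
    def b(self) -> np.ndarray:
        """Variant read counts."""
        return self.d - self.a


@dataclass
class PseudoSSM(SSM):
    """Read-count surrogate for a CNV, used to place the CNV on the tree."""

    source_cnv_id: str = ""


@dataclass
class CNV:
    """A subclonal copy-number call over a genomic interval.

    ``C`` is the total copy number in cells carrying the change; ``Cm``/``Cp``
    split it into the two parental copies (required for amplifications,
    ``C >= 2``, when an overlapping SSM may precede the CNV).  ``phi`` is the
    per-sample fraction of cells carrying the CNV.  ``support_depth`` sets the
    read depth of the derived pseudo-SSM, reflecting confidence in ``phi``.
    """

    id: str
    chrom: str
    start: int
    end: int
    C: int
    phi: np.ndarray
    Cm: Optional[int] = None
    Cp: Optional[int] = None
    support_depth: int = 60
    phased: bool = True

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.ndim != 1 or np.any(self.phi < 0) or np.any(self.phi > 1):
            raise InputError(f"CNV {self.id}: phi outside [0, 1]")
        if self.start >= self.end:
            raise InputError(f"CNV {self.id}: empty interval [{self.start}, {self.end})")
        if self.C < 0:
            raise InputError(f"CNV {self.id}: negative copy number")
        if self.support_depth < 1:
            raise InputError(f"CNV {self.id}: support_depth must be >= 1")
        if (self.Cm is None) != (self.Cp is None):
            raise InputError(f"CNV {self.id}: Cm and Cp must be given together")
        if self.Cm is None:
            # Only copy-number losses have a unique parental breakdown.
            if self.C >= 2:
                raise InputError(
                    f"CNV {self.id}: maternal/paternal breakdown required for C>=2"
                )
            self.Cm, self.Cp = 0, self.C
            self.phased = False
        elif self.Cm + self.Cp != self.C:
            raise InputError(f"CNV {self.id}: Cm+Cp={self.Cm + self.Cp} != C={self.C}")

    @property
    def n_samples(self) -> int:
        return len(self.phi)

    def contains(self, locus: Locus) -> bool:
        """Half-open containment of a point locus."""
        return locus is not None and locus.chrom == self.chrom and self.start <= locus.pos < self.end


def _round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (not banker's rounding)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def cnv_to_pseudo_ssm(cnv: CNV, epsilon: float = 0.0) -> PseudoSSM:
    """Convert a CNV into its pseudo-SSM read-count surrogate.

    Per sample the pseudo-SSM has total reads ``d = support_depth`` and
    variant reads ``b = round(d * phi / 2)``, i.e. the expected variant reads
    of a heterozygous mutation with population frequency phi.
    """
    d = np.full(cnv.n_samples, cnv.support_depth, dtype=np.int64)
    b = np.array([_round_half_away(cnv.support_depth * p / 2.0) for p in cnv.phi],
                 dtype=np.int64)
    return PseudoSSM(
        id=f"cnv_{cnv.id}",
        a=d - b,
        d=d,
        mu_r=1.0 - epsilon,
        mu_v=0.5,
        epsilon=epsilon,
        source_cnv_id=cnv.id,
    )


def default_support_depth(ssms: Sequence[SSM], multiplier: float = 2.0) -> int:
    """Pseudo-SSM depth as a multiple of the dataset's mean SSM read depth."""
    if not ssms:
        return 60
    mean_d = float(np.mean([s.d.mean() for s in ssms]))
    return max(1, _round_half_away(multiplier * mean_d))


def associate_ssms_to_cnvs(ssms: Sequence[SSM], cnvs: Sequence[CNV]) -> dict[str, list[str]]:
    """Map each SSM id to the CNVs whose intervals contain its locus.

    Containment is half-open ([start, end)); SSMs without a locus map to an
    empty list; several CNVs may cover one SSM and all are listed in input
    order.
    """
    trees: dict[str, IntervalTree] = {}
    order = {c.id: i for i, c in enumerate(cnvs)}
    for c in cnvs:
        trees.setdefault(c.chrom, IntervalTree()).addi(c.start, c.end, c.id)
    out: dict[str, list[str]] = {}
    for s in ssms:
        if s.locus is None or s.locus.chrom not in trees:
            out[s.id] = []
            continue
        hits = [iv.data for iv in trees[s.locus.chrom][s.locus.pos]]
        out[s.id] = sorted(hits, key=order.__getitem__)
    return out


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def _parse_counts(value, row_label: str, col: str) -> np.ndarray:
    try:
        return np.array([int(x) for x in str(value).split(",")], dtype=np.int64)
    except ValueError as exc:
        raise InputError(f"{row_label}: malformed {col} value {value!r}") from exc


def load_ssm_table(path) -> list[SSM]:
    """Read SSMs from a TSV with columns id, a, d and optional mu_r, mu_v,
    epsilon, chrom, pos, phase.  Multi-sample counts are comma-separated."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "a", "d"}
    if missing := required - set(df.columns):
        raise InputError(f"SSM table missing columns: {sorted(missing)}")
    ssms: list[SSM] = []
    n_samples = None
    for idx, row in df.iterrows():
        label = f"SSM row {idx} (id={row['id']})"
        a = _parse_counts(row["a"], label, "a")
        d = _parse_counts(row["d"], label, "d")
        epsilon = float(row["epsilon"]) if _has(row, "epsilon") else DEFAULT_EPSILON
        mu_r = float(row["mu_r"]) if _has(row, "mu_r") else 1.0 - epsilon
        mu_v = float(row["mu_v"]) if _has(row, "mu_v") else 0.5
        locus = None
        if _has(row, "chrom") and _has(row, "pos"):
            locus = Locus(str(row["chrom"]), int(row["pos"]))
        phase = str(row["phase"]) if _has(row, "phase") else UNKNOWN
        try:
            ssm = SSM(id=str(row["id"]), a=a, d=d, mu_r=mu_r, mu_v=mu_v,
                      locus=locus, phase=phase, epsilon=epsilon)
        except InputError as exc:
            raise InputError(f"{label}: {exc}") from exc
        if n_samples is None:
            n_samples = ssm.n_samples
        elif ssm.n_samples != n_samples:
            raise InputError(f"{label}: inconsistent sample count "
                             f"({ssm.n_samples} vs {n_samples})")
        ssms.append(ssm)
    return ssms


def _has(row, col) -> bool:
    return col in row.index and pd.notna(row[col]) and str(row[col]) != ""


def load_cnv_table(path) -> list[CNV]:
    """Read CNVs from a TSV with columns id, chrom, start, end, C, Cm, Cp,
    phi (comma-separated per sample), support_depth.  Cm/Cp may be blank only
    for copy-number losses (C < 2)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "chrom", "start", "end", "C", "phi"}
    if missing := required - set(df.columns):
        raise InputError(f"CNV table missing columns: {sorted(missing)}")
    cnvs: list[CNV] = []
    for idx, row in df.iterrows():
        label = f"CNV row {idx} (id={row['id']})"
        try:
            phi = np.array([float(x) for x in str(row["phi"]).split(",")])
        except ValueError as exc:
            raise InputError(f"{label}: malformed phi {row['phi']!r}") from exc
        Cm = int(row["Cm"]) if _has(row, "Cm") else None
        Cp = int(row["Cp"]) if _has(row, "Cp") else None
        depth = int(row["support_depth"]) if _has(row, "support_depth") else 60
        try:
            cnv = CNV(id=str(row["id"]), chrom=str(row["chrom"]),
                      start=int(row["start"]), end=int(row["end"]),
                      C=int(row["C"]), phi=phi, Cm=Cm, Cp=Cp, support_depth=depth)
        except (InputError, ValueError) as exc:
            raise InputError(f"{label}: {exc}") from exc
        cnvs.append(cnv)
    return cnvs


def write_ssm_table(ssms: Sequence[SSM], path) -> None:
    rows = []
    for s in ssms:
        rows.append({
            "id": s.id,
            "a": ",".join(map(str, s.a)),
            "d": ",".join(map(str, s.d)),
            "mu_r": s.mu_r,
            "mu_v": s.mu_v,
            "epsilon": s.epsilon,
            "chrom": s.locus.chrom if s.locus else "",
            "pos": s.locus.pos if s.locus else "",
            "phase": s.phase,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_cnv_table(cnvs: Sequence[CNV], path) -> None:
    rows = []
    for c in cnvs:
        rows.append({
            "id": c.id,
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "C": c.C,
            "Cm": c.Cm if c.phased else "",
            "Cp": c.Cp if c.phased else "",
            "phi": ",".join(repr(float(p)) for p in c.phi),
            "support_depth": c.support_depth,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
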