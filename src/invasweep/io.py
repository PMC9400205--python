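"""Readers/writers for the formats the pipeline touches, and the shared domain types.

All coordinates are 0-based half-open internally.  VCF positions (1-based) and
GFF3 intervals (1-based inclusive) are converted at the boundary, so window
arithmetic downstream never has to special-case a format convention.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1  # sentinel for a missing diploid dosage / GQ

_SEX_ALIASES = {
    "f": "F", "female": "F",
    "m": "M", "male": "M",
}

ANNOTATION_KEYS = ("QD", "MQ", "FS", "SOR", "MQRankSum", "ReadPosRankSum")


@dataclass(frozen=True)
class SampleMetadata:
    """One resequenced individual: id, population label and sex."""

    sample_id: str
    population: str
    sex: str = "unknown"  # F, M or unknown

    def __post_init__(self):
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if not self.population:
            raise ValueError(f"sample {self.sample_id!r}: population must be non-empty")
        if self.sex not in ("F", "M", "unknown"):
            raise ValueError(f"sample {self.sample_id!r}: sex must be F, M or unknown")


def _normalize_sex(raw) -> str:
    s = str(raw).strip().lower()
    if s in _SEX_ALIASES:
        return _SEX_ALIASES[s]
    return "unknown"


@dataclass
class GenotypeMatrix:
    """Sites x samples diploid dosage table with per-site metadata.

    ``dosage`` holds the alt-allele count per genotype (0/1/2) with ``MISSING``
    (-1) for uncalled cells; ``gq`` optionally holds genotype qualities with the
    same missing sentinel.  Positions are 1-based (VCF convention) and strictly
    increasing within each chromosome.
    """

    chrom: np.ndarray            # (m,) str
    pos: np.ndarray              # (m,) int64, 1-based
    ref: np.ndarray              # (m,) str
    alt: list[tuple[str, ...]]   # per-site alt alleles, >= 1 each
    dosage: np.ndarray           # (m, n) int8
    samples: list[str]
    gq: np.ndarray | None = None  # (m, n) int16 or None

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def validate(self) -> None:
        m, n = self.dosage.shape
        if not (len(self.chrom) == len(self.pos) == len(self.ref) == len(self.alt) == m):
            raise ValueError("per-site arrays have inconsistent lengths")
        if n != len(self.samples):
            raise ValueError("dosage columns do not match sample list")
        bad = (self.dosage < MISSING) | (self.dosage > 2)
        if bad.any():
            raise ValueError("dosage values must be in {0,1,2} or missing")
        if any(len(a) < 1 for a in self.alt):
            raise ValueError("every site needs at least one alt allele")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")

    def sample_indices(self, names: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} not in genotype matrix") from None

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset sites by boolean mask or integer index, preserving order."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=[self.alt[i] for i in index],
            dosage=self.dosage[index],
            samples=list(self.samples),
            gq=None if self.gq is None else self.gq[index],
        )


@dataclass
class SiteAnnotations:
    """Per-site INFO annotations used by the hard filter (NaN where absent)."""

    QD: np.ndarray
    MQ: np.ndarray
    FS: np.ndarray
    SOR: np.ndarray
    MQRankSum: np.ndarray
    ReadPosRankSum: np.ndarray

    @classmethod
    def empty(cls, n_sites: int) -> "SiteAnnotations":
        return cls(*(np.full(n_sites, np.nan) for _ in ANNOTATION_KEYS))

    @property
    def n_sites(self) -> int:
        return len(self.QD)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k) for k in ANNOTATION_KEYS}

    def take(self, index: np.ndarray) -> "SiteAnnotations":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return SiteAnnotations(**{k: v[index] for k, v in self.as_dict().items()})


@dataclass(frozen=True)
class GeneInterval:
    """A gene span in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    gene_id: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id!r}: need 0 <= start < end, "
                             f"got [{self.start}, {self.end})")
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")


@dataclass
class CoverageTrack:
    """Per-window mean read depth per sample over fixed-width tiling windows."""

    chrom: np.ndarray      # (w,) str
    start: np.ndarray      # (w,) int64, 0-based
    end: np.ndarray        # (w,) int64, half-open
    depth: np.ndarray      # (w, n) float, >= 0
    samples: list[str]
    width: int = 1000

    @property
    def n_windows(self) -> int:
        return len(self.start)

    def validate(self) -> None:
        if (self.depth < 0).any():
            raise ValueError("negative depth values")
        for c in pd.unique(self.chrom):
            i = np.flatnonzero(self.chrom == c)
            s, e = self.start[i], self.end[i]
            order = np.argsort(s)
            s, e = s[order], e[order]
            if (e - s > self.width).any() or (e <= s).any():
                raise ValueError(f"window wider than {self.width} bp on {c}")
            # every window but the chromosome-final one must be full width
            if ((e - s)[:-1] != self.width).any():
                raise ValueError(f"variable-width windows on {c}")
            if len(s) > 1 and (s[1:] != e[:-1]).any():
                raise ValueError(f"windows do not tile {c} (gap or overlap)")


# ---------------------------------------------------------------------------
# VCF

@dataclass(frozen=True)
class Region:
    chrom: str
    start: int = 0                 # 0-based half-open
    end: int = 2**62


def read_vcf(path: str | Path, region: Region | None = None
             ) -> tuple[GenotypeMatrix, SiteAnnotations]:
    """Read a VCF into a :class:`GenotypeMatrix` plus hard-filter annotations.

    Dosage is the count of alt alleles in GT regardless of phasing; ``./.``
    becomes missing.  INFO keys outside the six hard-filter annotations are
    ignored; absent keys yield NaN.  ``region`` restricts to one chromosome
    interval; a chromosome absent from the file yields an empty matrix.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as e:  # cyvcf2 raises bare exceptions on bad headers
        raise ValueError(f"cannot parse VCF {path}: {e}") from e

    samples = list(vcf.samples)
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[tuple[str, ...]] = []
    dosages: list[np.ndarray] = []
    gqs: list[np.ndarray] = []
    ann: dict[str, list[float]] = {k: [] for k in ANNOTATION_KEYS}
    saw_gq = False

    for var in vcf:
        if region is not None:
            if var.CHROM != region.chrom:
                continue
            if not (region.start < var.POS <= region.end):
                continue
        geno = var.genotypes  # [[a0, a1, phased], ...]
        row = np.empty(len(samples), dtype=np.int8)
        for j, g in enumerate(geno):
            alleles = g[:-1]
            if any(a < 0 for a in alleles):
                row[j] = MISSING
            else:
                row[j] = sum(1 for a in alleles if a > 0)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(tuple(var.ALT) if var.ALT else ("<NON_REF>",))
        dosages.append(row)
        try:
            q = var.format("GQ") if samples else None
        except KeyError:
            q = None
        if q is not None:
            saw_gq = True
            q = np.asarray(q).reshape(-1).astype(float)
            q = np.where(np.isfinite(q) & (q >= 0), q, MISSING)
            gqs.append(q.astype(np.int16))
        else:
            gqs.append(np.full(len(samples), MISSING, dtype=np.int16))
        for k in ANNOTATION_KEYS:
            v = var.INFO.get(k)
            ann[k].append(float(v) if v is not None else np.nan)
    vcf.close()

    m = len(poss)
    gm = GenotypeMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=alts,
        dosage=(np.vstack(dosages) if m else np.empty((0, len(samples)), np.int8)),
        samples=samples,
        gq=(np.vstack(gqs) if (m and saw_gq) else None),
    )
    annotations = SiteAnnotations(**{k: np.array(v, dtype=float) for k, v in ann.items()})
    return gm, annotations


_GT_STRINGS = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(gm: GenotypeMatrix, path: str | Path,
              annotations: SiteAnnotations | None = None,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write a minimal VCF v4.2 that :func:`read_vcf` reproduces exactly.

    Multi-allelic dosages of 1 and 2 are emitted as 0/1 and 1/1 against the
    first alt allele (the dosage, which is all downstream code consumes, is
    preserved; the allele identity of multi-allelic hets is not).
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=invasweep\n")
        lengths = dict(contig_lengths or {})
        for c in pd.unique(gm.chrom):
            n = lengths.get(str(c), int(gm.pos[gm.chrom == c].max()) if gm.n_sites else 1)
            fh.write(f"##contig=<ID={c},length={n}>\n")
        if annotations is not None:
            for k in ANNOTATION_KEYS:
                fh.write(f'##INFO=<ID={k},Number=1,Type=Float,Description="{k}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        has_gq = gm.gq is not None
        if has_gq:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(cols + gm.samples) + "\n")
        fmt = "GT:GQ" if has_gq else "GT"
        for i in range(gm.n_sites):
            if annotations is None:
                info = "."
            else:
                parts = [f"{k}={getattr(annotations, k)[i]:.6g}"
                         for k in ANNOTATION_KEYS
                         if np.isfinite(getattr(annotations, k)[i])]
                info = ";".join(parts) if parts else "."
            cells = []
            for j in range(gm.n_samples):
                gt = _GT_STRINGS[int(gm.dosage[i, j])]
                if has_gq:
                    q = int(gm.gq[i, j])
                    gt += f":{q}" if q >= 0 else ":."
                cells.append(gt)
            fh.write("\t".join([
                str(gm.chrom[i]), str(int(gm.pos[i])), ".", str(gm.ref[i]),
                ",".join(gm.alt[i]), ".", ".", info, fmt, *cells,
            ]) + "\n")


# ---------------------------------------------------------------------------
# Tables

def read_sample_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read a sample/population/sex TSV; sex strings are normalized to F/M/unknown."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"sample", "population", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: metadata missing columns {sorted(missing)}")
    if df["sample"].duplicated().any():
        dup = df["sample"][df["sample"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    return [
        SampleMetadata(row["sample"], row["population"], _normalize_sex(row["sex"]))
        for _, row in df.iterrows()
    ]


def write_sample_metadata(meta: Sequence[SampleMetadata], path: str | Path) -> None:
    pd.DataFrame(
        {"sample": [m.sample_id for m in meta],
         "population": [m.population for m in meta],
         "sex": [m.sex for m in meta]}
    ).to_csv(path, sep="\t", index=False)


_GFF_ID = re.compile(r"(?:^|;)ID=([^;]+)")


def read_intervals(path: str | Path, fmt: str | None = None) -> list[GeneInterval]:
    """Read gene intervals from BED4 (0-based half-open) or GFF3 (1-based
    inclusive, ``gene`` rows only); output is uniformly 0-based half-open."""
    path = Path(path)
    if fmt is None:
        fmt = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "bed"
    if fmt not in ("bed", "gff3"):
        raise ValueError(f"unknown interval format {fmt!r}")

    out: list[GeneInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if fmt == "bed":
                if len(f) < 4:
                    raise ValueError(f"{path}:{ln}: BED4 needs 4 columns")
                out.append(GeneInterval(f[0], int(f[1]), int(f[2]), f[3]))
            else:
                if len(f) < 9:
                    raise ValueError(f"{path}:{ln}: GFF3 needs 9 columns")
                if f[2] != "gene":
                    continue
                m = _GFF_ID.search(f[8])
                gid = m.group(1) if m else f"{f[0]}:{f[3]}-{f[4]}"
                out.append(GeneInterval(f[0], int(f[3]) - 1, int(f[4]), gid))
    return out


def write_bed(genes: Sequence[GeneInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\n")


def read_coverage(path: str | Path, width: int = 1000) -> CoverageTrack:
    """Read a per-window depth TSV (chrom, start, end, one column per sample)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise ValueError(f"{path}: coverage table missing column {col!r}")
    samples = [c for c in df.columns if c not in ("chrom", "start", "end")]
    if not samples:
        raise ValueError(f"{path}: coverage table has no sample columns")
    track = CoverageTrack(
        chrom=df["chrom"].to_numpy(dtype=object),
        start=df["start"].to_numpy(dtype=np.int64),
        end=df["end"].to_numpy(dtype=np.int64),
        depth=df[samples].to_numpy(dtype=float),
        samples=samples,
        width=width,
    )
    track.validate()
    return track


def write_coverage(track: CoverageTrack, path: str | Path) -> None:
    df = pd.DataFrame({"chrom": track.chrom, "start": track.start, "end": track.end})
    for j, s in enumerate(track.samples):
        df[s] = track.depth[:, j]
    df.to_csv(path, sep="\t", index=False)
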