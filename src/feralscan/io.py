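"""Genotype, interval, and population-map I/O.

Internal data model:

* :class:`GenotypeMatrix` — diploid alt-allele counts (0/1/2, ``MISSING``
  for no-call) for samples x biallelic SNP sites, with a site table of
  genomic coordinates and alleles.
* :class:`IntervalSet` — normalised genomic intervals (0-based half-open),
  used for domestication regions and called candidate regions.
* :class:`PopulationMap` — sample -> population / role / subgroup.

Coordinates are 0-based half-open internally; VCF I/O and human-readable
reports use 1-based positions.  Genotypes are unphased throughout: ``0/1``
and ``0|1`` are equivalent, and half-missing calls (``./1``) are treated
as missing.  Only biallelic SNPs are modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing diploid genotype call.
MISSING: int = -1

_VALID_BASES = frozenset("ACGT")
_VALID_ROLES = ("wild", "cultivated", "weedy", "outgroup")


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


class PopmapError(ValueError):
    """Raised for an invalid or incomplete population map."""


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls for samples x biallelic SNP sites.

    Parameters
    ----------
    sites
        DataFrame with columns ``chrom`` (str), ``pos`` (int, 1-based),
        ``ref`` and ``alt`` (single bases).  Row order defines
        ``site_id`` (0..S-1); positions must be strictly increasing
        within each chromosome.
    samples
        Ordered, unique sample identifiers.
    calls
        ``int8`` array of shape (n_samples, n_sites); each entry is the
        count of alt alleles (0, 1, 2) or :data:`MISSING`.
    """

    sites: pd.DataFrame
    samples: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample identifiers must be unique")
        ok = np.isin(self.calls, (0, 1, 2, MISSING))
        if not ok.all():
            bad = np.unique(self.calls[~ok])
            raise ValueError(f"invalid genotype codes: {bad.tolist()}")
        for col in ("chrom", "pos", "ref", "alt"):
            if col not in self.sites.columns:
                raise ValueError(f"sites table missing column {col!r}")
        pos = self.sites["pos"].to_numpy()
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            p = grp["pos"].to_numpy()
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
        for col in ("ref", "alt"):
            vals = self.sites[col]
            if not vals.isin(list(_VALID_BASES)).all():
                raise ValueError(f"{col} alleles must be single bases from ACGT")
        if (self.sites["ref"] == self.sites["alt"]).any():
            raise ValueError("ref and alt alleles must differ")
        _ = pos  # positions validated per-chromosome above

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, names: Sequence[str]) -> np.ndarray:
        """Row indices of ``names`` in sample order; unknown name -> KeyError."""
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in genotype matrix") from None

    def subset_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_indices(names)
        return GenotypeMatrix(self.sites.copy(), list(names), self.calls[idx])


@dataclass
class IntervalSet:
    """A normalised set of genomic intervals, 0-based half-open.

    ``df`` has columns ``chrom`` (str), ``start``, ``end`` (int bp).
    After :meth:`normalize`, intervals are sorted by (chrom, start),
    non-overlapping (adjacent intervals merged) and satisfy start < end.
    """

    df: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end"])
    )

    @classmethod
    def from_tuples(cls, intervals: Iterable[tuple[str, int, int]]) -> "IntervalSet":
        rows = list(intervals)
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        return cls(df).normalize()

    def normalize(self) -> "IntervalSet":
        """Sort and merge overlapping or bookended intervals (idempotent)."""
        if self.df.empty:
            return IntervalSet()
        df = self.df.copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValueError(
                f"invalid interval {bad['chrom']}:{bad['start']}-{bad['end']} "
                "(start must be < end)"
            )
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
        out: list[tuple[str, int, int]] = []
        for chrom, grp in df.groupby("chrom", sort=True):
            cur_s = cur_e = None
            for s, e in zip(grp["start"], grp["end"]):
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s <= cur_e:  # overlap or bookend
                    cur_e = max(cur_e, e)
                else:
                    out.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            out.append((chrom, cur_s, cur_e))
        return IntervalSet(pd.DataFrame(out, columns=["chrom", "start", "end"]))

    @property
    def total_length(self) -> int:
        if self.df.empty:
            return 0
        return int((self.df["end"] - self.df["start"]).sum())

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        """Base-pair intersection of two normalised interval sets."""
        a, b = self.normalize().df, other.normalize().df
        out: list[tuple[str, int, int]] = []
        for chrom in sorted(set(a["chrom"]).intersection(b["chrom"])):
            ai = a[a["chrom"] == chrom].to_numpy()
            bi = b[b["chrom"] == chrom].to_numpy()
            i = j = 0
            while i < len(ai) and j < len(bi):
                s = max(ai[i][1], bi[j][1])
                e = min(ai[i][2], bi[j][2])
                if s < e:
                    out.append((chrom, int(s), int(e)))
                if ai[i][2] <= bi[j][2]:
                    i += 1
                else:
                    j += 1
        return IntervalSet(pd.DataFrame(out, columns=["chrom", "start", "end"]))

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(pd.concat([self.df, other.df], ignore_index=True)).normalize()

    def contains(self, chrom: Sequence[str], pos0: Sequence[int]) -> np.ndarray:
        """Boolean membership for 0-based positions (vectorised per chrom)."""
        chrom = np.asarray(chrom)
        pos0 = np.asarray(pos0, dtype=np.int64)
        res = np.zeros(len(pos0), dtype=bool)
        norm = self.normalize().df
        for c, grp in norm.groupby("chrom", sort=False):
            mask = chrom == c
            if not mask.any():
                continue
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            idx = np.searchsorted(starts, pos0[mask], side="right") - 1
            inside = (idx >= 0) & (pos0[mask] < ends[np.clip(idx, 0, None)])
            res[mask] = inside
        return res

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class PopulationMap:
    """Sample -> population label, role and optional subgroup.

    ``df`` has columns ``sample``, ``population``, ``role`` and
    ``subgroup`` (may be empty strings).  Roles are restricted to
    wild | cultivated | weedy | outgroup.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample", "population", "role"}
        missing = required - set(self.df.columns)
        if missing:
            raise PopmapError(f"population map missing columns: {sorted(missing)}")
        if "subgroup" not in self.df.columns:
            self.df = self.df.assign(subgroup="")
        self.df = self.df.reset_index(drop=True)
        dupes = self.df["sample"][self.df["sample"].duplicated()]
        if len(dupes):
            raise PopmapError(f"duplicate samples in population map: {sorted(set(dupes))}")
        bad = sorted(set(self.df["role"]) - set(_VALID_ROLES))
        if bad:
            raise PopmapError(
                f"unknown roles {bad}; allowed roles are {list(_VALID_ROLES)}"
            )

    def samples_for(
        self,
        *,
        role: str | None = None,
        population: str | None = None,
        subgroup: str | None = None,
    ) -> list[str]:
        df = self.df
        if role is not None:
            df = df[df["role"] == role]
        if population is not None:
            df = df[df["population"] == population]
        if subgroup is not None:
            df = df[df["subgroup"] == subgroup]
        return df["sample"].tolist()

    def resolve_group(self, label: str) -> list[str]:
        """Samples matching ``label`` as a population, then role, then subgroup."""
        for key in ("population", "role", "subgroup"):
            hit = self.df[self.df[key] == label]
            if len(hit):
                return hit["sample"].tolist()
        avail = sorted(
            set(self.df["population"]) | set(self.df["role"]) | set(self.df["subgroup"]) - {""}
        )
        raise KeyError(f"group {label!r} not found; available labels: {avail}")

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# VCF


def read_vcf(
    path: str | Path,
    min_call_rate: float = 0.0,
    biallelic_only: bool = True,
) -> GenotypeMatrix:
    """Read genotypes from a VCF (plain or bgzipped) into a GenotypeMatrix.

    Only biallelic SNP records are retained when ``biallelic_only``;
    indels and multiallelic records are dropped with a logged count.
    Sites whose fraction of called samples falls below ``min_call_rate``
    are dropped.  Diploid GTs are mapped to alt-allele counts; any
    genotype with a missing allele is coded :data:`MISSING`.
    """
    from cyvcf2 import VCF

    if not 0.0 <= min_call_rate <= 1.0:
        raise ValueError("min_call_rate must be in [0, 1]")
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # htslib raises bare exceptions on bad headers
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise VcfParseError(f"VCF {path} contains no samples")

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[np.ndarray] = []
    n_skipped_nonsnp = 0
    n_skipped_multi = 0
    n_skipped_callrate = 0
    record_no = 0
    try:
        for var in vcf:
            record_no += 1
            alt_list = var.ALT
            if biallelic_only and len(alt_list) != 1:
                n_skipped_multi += 1
                continue
            if len(alt_list) != 1:
                n_skipped_multi += 1
                continue
            ref, alt = var.REF, alt_list[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in _VALID_BASES or alt not in _VALID_BASES:
                n_skipped_nonsnp += 1
                continue
            alleles = np.asarray(var.genotypes, dtype=np.int16)[:, :2]
            calls = alleles.sum(axis=1).astype(np.int8)
            # any missing allele (including half-missing ./1) -> MISSING
            calls[(alleles < 0).any(axis=1)] = MISSING
            called_frac = float(np.mean(calls != MISSING))
            if called_frac < min_call_rate:
                n_skipped_callrate += 1
                continue
            chroms.append(var.CHROM)
            poss.append(var.POS)
            refs.append(ref)
            alts.append(alt)
            rows.append(calls)
    except Exception as exc:
        raise VcfParseError(
            f"malformed VCF record near data line {record_no + 1} in {path}: {exc}"
        ) from exc

    if n_skipped_nonsnp or n_skipped_multi or n_skipped_callrate:
        logger.info(
            "read_vcf(%s): dropped %d non-SNP, %d multiallelic, %d low-call-rate records",
            path, n_skipped_nonsnp, n_skipped_multi, n_skipped_callrate,
        )
    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    calls = (
        np.vstack(rows).T.astype(np.int8)
        if rows
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(sites, samples, calls)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT-only genotypes.

    The header is fixed (no timestamp) so identical matrices produce
    byte-identical files.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=feralscan\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(G.sites["chrom"]):
            maxp = int(G.sites.loc[G.sites["chrom"] == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={maxp + 1}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(G.samples) + "\n")
        calls = G.calls
        for j, (chrom, pos, ref, alt) in enumerate(
            zip(G.sites["chrom"], G.sites["pos"], G.sites["ref"], G.sites["alt"])
        ):
            gts = "\t".join(_GT_STR[int(c)] for c in calls[:, j])
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# BED intervals


def read_intervals(path: str | Path) -> IntervalSet:
    """Read a BED3+ file (0-based half-open) into a normalised IntervalSet."""
    rows: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval {chrom}:{start}-{end}"
                )
            rows.append((chrom, start, end))
    if not rows:
        return IntervalSet()
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"])).normalize()


def write_intervals(intervals: IntervalSet, path: str | Path) -> None:
    """Write an IntervalSet as BED3."""
    with open(path, "w") as fh:
        for chrom, start, end in intervals.df.itertuples(index=False):
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# Population map


def read_popmap(path: str | Path, samples: Sequence[str] | None = None) -> PopulationMap:
    """Read a TSV population map (columns: sample, population, role[, subgroup]).

    When ``samples`` is given, every one of them must appear in the map;
    missing samples raise a :class:`PopmapError` listing them.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    pm = PopulationMap(df)
    if samples is not None:
        missing = sorted(set(samples) - set(pm.df["sample"]))
        if missing:
            raise PopmapError(
                f"samples present in genotypes but absent from population map: {missing}"
            )
    return pm


def write_popmap(pm: PopulationMap, path: str | Path) -> None:
    pm.df.to_csv(path, sep="\t", index=False)
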