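"""Haploid genotype matrix and callable-region mask containers.

Conventions follow the standard formats exactly: VCF positions are 1-based,
BED intervals are 0-based half-open.  The genotype matrix is binary after
polarisation — 0 ancestral, 1 derived, -1 missing — one haploid call per
sample per site.  Two alternative alleles at the same position are carried
as two independent sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

__all__ = ["GenotypeMatrix", "RegionMask", "MaskError"]

MISSING = -1


class MaskError(ValueError):
    pass


@dataclass
class RegionMask:
    """Sorted, disjoint 0-based half-open intervals on chromosome Y."""

    intervals: np.ndarray  # (n, 2) int64

    def __post_init__(self):
        iv = np.asarray(self.intervals, dtype=np.int64).reshape(-1, 2)
        if len(iv):
            if np.any(iv[:, 0] >= iv[:, 1]):
                raise MaskError("mask has empty or inverted intervals")
            order = np.lexsort((iv[:, 1], iv[:, 0]))
            if not np.array_equal(order, np.arange(len(iv))):
                raise MaskError("mask intervals not sorted")
            if np.any(iv[1:, 0] < iv[:-1, 1]):
                raise MaskError("mask intervals overlap")
        self.intervals = iv

    # ------------------------------------------------------------ constructors
    @classmethod
    def from_intervals(cls, intervals, merge: bool = False) -> "RegionMask":
        iv = np.asarray(list(intervals), dtype=np.int64).reshape(-1, 2)
        if merge and len(iv):
            iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
            out = [iv[0].tolist()]
            for s, e in iv[1:]:
                if s <= out[-1][1]:
                    out[-1][1] = max(out[-1][1], e)
                else:
                    out.append([s, e])
            iv = np.asarray(out, dtype=np.int64)
        return cls(iv)

    @classmethod
    def empty(cls) -> "RegionMask":
        return cls(np.empty((0, 2), dtype=np.int64))

    @classmethod
    def full(cls, length: int) -> "RegionMask":
        return cls(np.array([[0, int(length)]], dtype=np.int64))

    # ------------------------------------------------------------ arithmetic
    @property
    def length(self) -> int:
        """Total callable bases."""
        if not len(self.intervals):
            return 0
        return int((self.intervals[:, 1] - self.intervals[:, 0]).sum())

    def __len__(self) -> int:
        return len(self.intervals)

    def union(self, other: "RegionMask") -> "RegionMask":
        both = np.vstack([self.intervals, other.intervals])
        return RegionMask.from_intervals(both, merge=True)

    def intersect(self, other: "RegionMask") -> "RegionMask":
        out = []
        i = j = 0
        a, b = self.intervals, other.intervals
        while i < len(a) and j < len(b):
            s = max(a[i, 0], b[j, 0])
            e = min(a[i, 1], b[j, 1])
            if s < e:
                out.append((s, e))
            if a[i, 1] <= b[j, 1]:
                i += 1
            else:
                j += 1
        return RegionMask.from_intervals(out)

    def subtract(self, other: "RegionMask") -> "RegionMask":
        out = []
        j = 0
        b = other.intervals
        for s, e in self.intervals:
            cur = s
            while j < len(b) and b[j, 1] <= cur:
                j += 1
            k = j
            while k < len(b) and b[k, 0] < e:
                if b[k, 0] > cur:
                    out.append((cur, b[k, 0]))
                cur = max(cur, b[k, 1])
                k += 1
            if cur < e:
                out.append((cur, e))
        return RegionMask.from_intervals(out)

    def contains_positions(self, positions_1based) -> np.ndarray:
        """Boolean membership of 1-based positions (POS p covers base [p-1, p))."""
        pos0 = np.asarray(positions_1based, dtype=np.int64) - 1
        if not len(self.intervals):
            return np.zeros(pos0.shape, dtype=bool)
        idx = np.searchsorted(self.intervals[:, 0], pos0, side="right") - 1
        ok = idx >= 0
        inside = np.zeros(pos0.shape, dtype=bool)
        inside[ok] = pos0[ok] < self.intervals[idx[ok], 1]
        return inside

    def interval_containing(self, position_1based: int) -> tuple[int, int] | None:
        """The (start, end) interval covering a 1-based position, or None."""
        inside = self.contains_positions([position_1based])
        if not inside[0]:
            return None
        idx = np.searchsorted(self.intervals[:, 0], position_1based - 1, side="right") - 1
        return int(self.intervals[idx, 0]), int(self.intervals[idx, 1])

    def __eq__(self, other) -> bool:
        return isinstance(other, RegionMask) and np.array_equal(self.intervals, other.intervals)

    # ------------------------------------------------------------ BED IO
    def to_bed(self, path, chrom: str = "Y") -> None:
        df = pd.DataFrame(
            {"chrom": chrom, "start": self.intervals[:, 0], "end": self.intervals[:, 1]}
        )
        df.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path) -> "RegionMask":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end"], usecols=[0, 1, 2])
        return cls.from_intervals(df[["start", "end"]].to_numpy(), merge=True)

    def __repr__(self):  # pragma: no cover
        return f"<RegionMask {len(self.intervals)} intervals, {self.length} bp>"


@dataclass
class GenotypeMatrix:
    """Haploid sample x site call matrix (0 ancestral / 1 derived / -1 missing)."""

    samples: list[str]
    positions: np.ndarray  # (m,) int64, 1-based, non-decreasing
    calls: np.ndarray  # (n_samples, m) int8
    platforms: dict[str, str] = field(default_factory=dict)
    ref: np.ndarray | None = None  # per-site ancestral allele (str)
    alt: np.ndarray | None = None  # per-site derived allele (str)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.positions)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.positions)} sites"
            )
        if len(self.positions) > 1 and np.any(np.diff(self.positions) < 0):
            order = np.argsort(self.positions, kind="stable")
            self.positions = self.positions[order]
            self.calls = self.calls[:, order]
            if self.ref is not None:
                self.ref = np.asarray(self.ref)[order]
            if self.alt is not None:
                self.alt = np.asarray(self.alt)[order]

    # ------------------------------------------------------------ basic views
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise KeyError(f"unknown sample {name!r}") from None

    def column(self, name: str) -> np.ndarray:
        return self.calls[self.sample_index(name)]

    def derived_counts(self) -> np.ndarray:
        return (self.calls == 1).sum(axis=0)

    def missing_fraction(self) -> np.ndarray:
        return (self.calls == MISSING).sum(axis=0) / self.n_samples

    def carriers(self, site_index: int) -> frozenset:
        idx = np.nonzero(self.calls[:, site_index] == 1)[0]
        return frozenset(self.samples[i] for i in idx)

    def missing_samples(self, site_index: int) -> frozenset:
        idx = np.nonzero(self.calls[:, site_index] == MISSING)[0]
        return frozenset(self.samples[i] for i in idx)

    # ------------------------------------------------------------ subsetting
    def take_sites(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            positions=self.positions[index],
            calls=self.calls[:, index],
            platforms=dict(self.platforms),
            ref=None if self.ref is None else np.asarray(self.ref)[index],
            alt=None if self.alt is None else np.asarray(self.alt)[index],
        )

    def drop_sites_at(self, positions) -> "GenotypeMatrix":
        drop = np.isin(self.positions, np.asarray(positions, dtype=np.int64))
        return self.take_sites(~drop)

    def take_samples(self, names: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(n) for n in names]
        return GenotypeMatrix(
            samples=list(names),
            positions=self.positions.copy(),
            calls=self.calls[idx],
            platforms={n: self.platforms[n] for n in names if n in self.platforms},
            ref=None if self.ref is None else np.asarray(self.ref).copy(),
            alt=None if self.alt is None else np.asarray(self.alt).copy(),
        )

    def drop_samples(self, names) -> "GenotypeMatrix":
        drop = set(names)
        return self.take_samples([s for s in self.samples if s not in drop])

    def tip_states(self) -> dict[str, np.ndarray]:
        """Per-sample call arrays keyed by sample name (for parsimony)."""
        return {s: self.calls[i] for i, s in enumerate(self.samples)}

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeMatrix)
            and self.samples == other.samples
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.calls, other.calls)
        )

    # ------------------------------------------------------------ VCF IO
    def to_vcf(self, path, chrom: str = "Y") -> None:
        """Write a minimal haploid VCF (GT 0 / 1 / .)."""
        ref = self.ref if self.ref is not None else np.full(self.n_sites, "A", dtype=object)
        alt = self.alt if self.alt is not None else np.full(self.n_sites, "G", dtype=object)
        gt_char = np.empty(self.calls.shape, dtype="U1")
        gt_char[self.calls == 0] = "0"
        gt_char[self.calls == 1] = "1"
        gt_char[self.calls == MISSING] = "."
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={chrom}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for s in self.samples:
                plat = self.platforms.get(s)
                if plat:
                    fh.write(f"##SAMPLE=<ID={s},Platform={plat}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
            fh.write("\t".join(self.samples) + "\n")
            for j in range(self.n_sites):
                row = "\t".join(gt_char[:, j])
                fh.write(
                    f"{chrom}\t{self.positions[j]}\t.\t{ref[j]}\t{alt[j]}\t.\tPASS\t.\tGT\t{row}\n"
                )

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        """Read a haploid (or haploid-coded diploid) VCF with pysam.

        Multi-allelic records are split into one site per alternative allele.
        """
        platforms: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("##"):
                    break
                if line.startswith("##SAMPLE=<"):
                    body = line.strip()[10:-1]
                    fields = dict(kv.split("=", 1) for kv in body.split(",") if "=" in kv)
                    if "ID" in fields and "Platform" in fields:
                        platforms[fields["ID"]] = fields["Platform"]
        vf = pysam.VariantFile(path)
        samples = list(vf.header.samples)
        positions, ref, alt, columns = [], [], [], []
        for rec in vf:
            alts = rec.alts or ()
            for ai, a in enumerate(alts, start=1):
                calls = np.empty(len(samples), dtype=np.int8)
                for si, s in enumerate(samples):
                    gt = rec.samples[s].get("GT")
                    allele = gt[0] if gt else None
                    if allele is None:
                        calls[si] = MISSING
                    else:
                        calls[si] = 1 if allele == ai else 0
                positions.append(rec.pos)
                ref.append(rec.ref)
                alt.append(a)
                columns.append(calls)
        vf.close()
        calls = (
            np.stack(columns, axis=1) if columns else np.empty((len(samples), 0), dtype=np.int8)
        )
        return cls(
            samples=samples,
            positions=np.asarray(positions, dtype=np.int64),
            calls=calls,
            platforms=platforms,
            ref=np.asarray(ref, dtype=object),
            alt=np.asarray(alt, dtype=object),
        )

    def __repr__(self):  # pragma: no cover
        return f"<GenotypeMatrix {self.n_samples} samples x {self.n_sites} sites>"
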