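"""Genotype containers and text-format IO (PLINK PED/MAP, minimal VCF).

Calls are coded per marker as 0 = homozygous reference, 1 = heterozygous,
2 = homozygous alternate, -1 = missing. The marker map is an ordered
table of (chrom, pos, id) with positions strictly increasing within each
chromosome. VCF reading goes through cyvcf2; writing emits a minimal
GT-only VCF.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMap",
    "GenotypeMatrix",
    "read_ped_map",
    "read_vcf",
]


@dataclass
class MarkerMap:
    df: pd.DataFrame  # columns: chrom, pos, id

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        for chrom, grp in df.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"marker positions not strictly increasing on {chrom}"
                )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero((self.df["chrom"] == chrom).to_numpy())
        return slice(int(idx[0]), int(idx[-1]) + 1)


@dataclass
class GenotypeMatrix:
    """Individuals x ordered biallelic markers with a linked map."""

    samples: list[str]
    calls: np.ndarray      # (n_samples, n_markers) int8
    markers: MarkerMap

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )

    def sample_index(self, ind: str) -> int:
        try:
            return self.samples.index(str(ind))
        except ValueError:
            raise KeyError(f"unknown individual id: {ind!r}") from None

    def row(self, ind: str) -> np.ndarray:
        return self.calls[self.sample_index(ind)]

    def missingness(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return (self.calls < 0).mean(axis=0)

    def subset_markers(self, keep_ids: Sequence[str]) -> "GenotypeMatrix":
        keep = set(keep_ids)
        mask = self.markers.df["id"].isin(keep).to_numpy()
        return GenotypeMatrix(
            samples=list(self.samples),
            calls=self.calls[:, mask],
            markers=MarkerMap(self.markers.df[mask]),
        )

    # -- PLINK PED/MAP -----------------------------------------------------
    def write_ped_map(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        mapdf = self.markers.df
        with open(prefix.with_suffix(".map"), "w") as fh:
            for _, row in mapdf.iterrows():
                fh.write(f"{row['chrom']}\t{row['id']}\t0\t{row['pos']}\n")
        coded = {0: "A A", 1: "A B", 2: "B B", -1: "0 0"}
        with open(prefix.with_suffix(".ped"), "w") as fh:
            for i, ind in enumerate(self.samples):
                geno = " ".join(coded[int(c)] for c in self.calls[i])
                fh.write(f"FAM {ind} 0 0 0 -9 {geno}\n")

    # -- minimal VCF -------------------------------------------------------
    def write_vcf(self, path: str | Path) -> None:
        gt = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for chrom in self.markers.chroms:
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.samples)
                + "\n"
            )
            for j, (_, row) in enumerate(self.markers.df.iterrows()):
                cells = "\t".join(gt[int(c)] for c in self.calls[:, j])
                fh.write(
                    f"{row['chrom']}\t{row['pos'] + 1}\t{row['id']}\t"
                    f"A\tB\t.\tPASS\t.\tGT\t{cells}\n"
                )


def read_ped_map(prefix: str | Path) -> GenotypeMatrix:
    """Read a whitespace-delimited PLINK text fileset."""
    prefix = Path(prefix)
    mapdf = pd.read_csv(
        prefix.with_suffix(".map"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos"],
        dtype={"chrom": str, "id": str},
    )
    markers = MarkerMap(mapdf[["chrom", "pos", "id"]])
    samples: list[str] = []
    rows: list[np.ndarray] = []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            samples.append(parts[1])
            alleles = parts[6:]
            a = np.asarray(alleles[0::2])
            b = np.asarray(alleles[1::2])
            calls = np.where(
                (a == "0") | (b == "0"),
                -1,
                (a == "B").astype(np.int8) + (b == "B").astype(np.int8),
            ).astype(np.int8)
            rows.append(calls)
    return GenotypeMatrix(
        samples=samples, calls=np.vstack(rows), markers=markers
    )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read GT calls from a VCF via cyvcf2 (positions stored 0-based)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    calls: list[np.ndarray] = []
    for j, var in enumerate(vcf):
        rows.append((var.CHROM, var.POS - 1, var.ID or f"m{j}"))
        gts = var.gt_types  # 0=hom_ref, 1=het, 2=unknown, 3=hom_alt
        col = np.where(
            gts == 3, 2, np.where(gts == 2, -1, gts)
        ).astype(np.int8)
        calls.append(col)
    markers = MarkerMap(pd.DataFrame(rows, columns=["chrom", "pos", "id"]))
    return GenotypeMatrix(
        samples=samples,
        calls=np.asarray(calls, dtype=np.int8).T,
        markers=markers,
    )
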