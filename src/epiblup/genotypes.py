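"""Genotype matrix container and plain-text I/O (minimal VCF and TSV)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

_VALID_DOSAGES = frozenset({0, 1, 2})


@dataclass
class GenotypeMatrix:
    """Animals x SNPs biallelic dosage matrix with IDs and optional positions.

    Dosages count copies of the alternate allele, so each entry is 0, 1 or 2
    with no missing values. ``positions`` is an optional list of
    ``(chromosome, bp)`` pairs aligned with ``snp_ids``.
    """

    animal_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray
    positions: list[tuple[str, int]] | None = None
    _freqs: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (animals x SNPs) matrix")
        n, m = self.dosages.shape
        if n != len(self.animal_ids) or m != len(self.snp_ids):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.animal_ids)} animals x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.animal_ids)) != n:
            raise ValueError("animal_ids contains duplicates")
        if len(set(self.snp_ids)) != m:
            raise ValueError("snp_ids contains duplicates")
        bad = ~np.isin(self.dosages, (0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid dosage {self.dosages[i, j]!r} for animal "
                f"{self.animal_ids[i]!r}, SNP {self.snp_ids[j]!r}: must be 0, 1 or 2"
            )
        if self.positions is not None and len(self.positions) != m:
            raise ValueError("positions must align with snp_ids")

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def genotype_freqs(self) -> np.ndarray:
        """Observed per-SNP genotype frequencies, shape (n_snps, 3).

        Columns are the frequencies of dosage 0, 1 and 2; rows sum to 1.
        """
        if self._freqs is None:
            n = self.n_animals
            self._freqs = np.stack(
                [(self.dosages == g).sum(axis=0) / n for g in (0, 1, 2)], axis=1
            )
        return self._freqs

    @property
    def allele_freqs(self) -> np.ndarray:
        """Alternate-allele frequency per SNP."""
        return self.dosages.mean(axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        q = self.allele_freqs
        return np.minimum(q, 1.0 - q)

    def het_percent(self) -> np.ndarray:
        """Per-animal percentage of heterozygous SNPs: 100 * mean(dosage == 1)."""
        return 100.0 * (self.dosages == 1).mean(axis=1)

    def subset_animals(self, indices: np.ndarray) -> "GenotypeMatrix":
        indices = np.asarray(indices)
        return GenotypeMatrix(
            animal_ids=[self.animal_ids[i] for i in indices],
            snp_ids=list(self.snp_ids),
            dosages=self.dosages[indices],
            positions=None if self.positions is None else list(self.positions),
        )

    def subset_snps(self, indices: np.ndarray) -> "GenotypeMatrix":
        indices = np.asarray(indices)
        return GenotypeMatrix(
            animal_ids=list(self.animal_ids),
            snp_ids=[self.snp_ids[j] for j in indices],
            dosages=self.dosages[:, indices],
            positions=None
            if self.positions is None
            else [self.positions[j] for j in indices],
        )


def filter_maf(g: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Drop monomorphic and sub-MAF SNPs; fail if nothing survives."""
    keep = np.flatnonzero((g.maf >= threshold) & (g.maf > 0))
    if keep.size == 0:
        raise ValueError(
            f"all {g.n_snps} SNPs removed by the MAF >= {threshold} filter"
        )
    if keep.size < g.n_snps:
        logger.info("MAF filter removed %d of %d SNPs", g.n_snps - keep.size, g.n_snps)
    return g.subset_snps(keep)


# ---------------------------------------------------------------------------
# I/O
#
# VCF: minimal biallelic dialect with a GT FORMAT field, diploid, phased or
# unphased. TSV: header row "animal_id\t<snp>...", one row per animal; SNP
# column headers are "id" or "id:chrom:pos" so that positions round-trip.
# ---------------------------------------------------------------------------


def write_genotypes(g: GenotypeMatrix, path: str | Path, format: str = "vcf") -> None:
    path = Path(path)
    if format == "vcf":
        _write_vcf(g, path)
    elif format == "tsv":
        _write_tsv(g, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def read_genotypes(
    path: str | Path, format: str = "vcf", missing_policy: str = "fail"
) -> GenotypeMatrix:
    """Read genotypes; ``missing_policy`` is 'fail' or 'impute_mode' (VCF only)."""
    path = Path(path)
    if format == "vcf":
        return _read_vcf(path, missing_policy=missing_policy)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1"}


def _write_vcf(g: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.animal_ids)
            + "\n"
        )
        for j, snp in enumerate(g.snp_ids):
            chrom, pos = ("1", j + 1) if g.positions is None else g.positions[j]
            gts = "\t".join(_GT_CODE[d] for d in g.dosages[:, j])
            fh.write(f"{chrom}\t{pos}\t{snp}\tA\tG\t.\t.\t.\tGT\t{gts}\n")


def _read_vcf(path: Path, missing_policy: str = "fail") -> GenotypeMatrix:
    from cyvcf2 import VCF

    if missing_policy not in ("fail", "impute_mode"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    vcf = VCF(str(path), gts012=True)  # gt_types: 0/1/2 dosage, 3 = missing
    animal_ids = list(vcf.samples)
    snp_ids: list[str] = []
    positions: list[tuple[str, int]] = []
    rows: list[np.ndarray] = []
    n_multiallelic = 0
    for idx, variant in enumerate(vcf):
        if len(variant.ALT) != 1:
            n_multiallelic += 1
            continue
        dose = np.asarray(variant.gt_types, dtype=np.int16)
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        missing = np.flatnonzero(dose == 3)
        if missing.size:
            if missing_policy == "fail":
                raise ValueError(
                    f"missing GT at record {vid} for sample "
                    f"{animal_ids[missing[0]]}"
                )
            observed = np.delete(dose, missing)
            vals, counts = np.unique(observed, return_counts=True)
            dose[missing] = vals[np.argmax(counts)] if vals.size else 0
        snp_ids.append(vid)
        positions.append((variant.CHROM, variant.POS))
        rows.append(dose)
    vcf.close()
    if n_multiallelic:
        logger.warning("skipped %d multi-allelic record(s)", n_multiallelic)
    if not rows:
        raise ValueError(f"no biallelic records found in {path}")
    return GenotypeMatrix(
        animal_ids=animal_ids,
        snp_ids=snp_ids,
        dosages=np.stack(rows, axis=1),
        positions=positions,
    )


def _write_tsv(g: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        if g.positions is None:
            header = list(g.snp_ids)
        else:
            header = [
                f"{s}:{c}:{p}" for s, (c, p) in zip(g.snp_ids, g.positions)
            ]
        fh.write("animal_id\t" + "\t".join(header) + "\n")
        for i, aid in enumerate(g.animal_ids):
            fh.write(aid + "\t" + "\t".join(map(str, g.dosages[i])) + "\n")


def _read_tsv(path: Path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "animal_id":
            raise ValueError(f"{path}: first TSV column must be 'animal_id'")
        snp_ids: list[str] = []
        positions: list[tuple[str, int]] | None = []
        for col in header[1:]:
            parts = col.split(":")
            if len(parts) == 3:
                snp_ids.append(parts[0])
                positions.append((parts[1], int(parts[2])))
            else:
                snp_ids.append(col)
                positions = None if positions == [] or positions is None else positions
        if positions is not None and len(positions) != len(snp_ids):
            positions = None
        animal_ids: list[str] = []
        rows: list[list[int]] = []
        for r, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}: line {r} has {len(fields)} fields, expected {len(header)}"
                )
            animal_ids.append(fields[0])
            row = []
            for c, tok in enumerate(fields[1:], start=2):
                try:
                    v = int(tok)
                except ValueError:
                    v = -1
                if v not in _VALID_DOSAGES:
                    raise ValueError(
                        f"{path}: invalid dosage {tok!r} at row {r} "
                        f"(animal {fields[0]!r}), column {c} (SNP {snp_ids[c - 2]!r})"
                    )
                row.append(v)
            rows.append(row)
    return GenotypeMatrix(
        animal_ids=animal_ids,
        snp_ids=snp_ids,
        dosages=np.array(rows, dtype=np.int16),
        positions=positions,
    )
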