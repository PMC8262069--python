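"""Orthogonal (NOIA) marker codings and trace-scaled genomic relationship
matrices.

The additive and dominance codings use observed genotype frequencies of the
analysed animal set, which makes the two per-SNP coding columns statistically
orthogonal. Relationship matrices: A = scale(W_a W_a'), D = scale(W_d W_d'),
and the epistatic kernels AA, AD, DD as trace-scaled Hadamard products.
An exact additive-by-additive construction that sums each unordered SNP pair
once (excluding same-SNP squares) is provided for comparison with the
Hadamard approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from epiblup.genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

EPISTATIC_PARENTS = {"AA": ("A", "A"), "AD": ("A", "D"), "DD": ("D", "D")}


class DegenerateSNPError(ValueError):
    """Raised for SNPs whose coding is undefined (monomorphic or degenerate)."""


def noia_additive_coding(genotype_freqs: tuple[float, float, float]) -> tuple[float, float, float]:
    """Centered allele-count codes for dosages (0, 1, 2).

    Returns (-m, 1-m, 2-m) with m = p1 + 2*p2, the population mean dosage,
    so the frequency-weighted mean of the codes is zero.
    """
    p0, p1, p2 = genotype_freqs
    if p0 >= 1.0 or p2 >= 1.0 or (p1 == 0 and (p0 == 0 or p2 == 0)):
        raise DegenerateSNPError(f"monomorphic SNP: genotype freqs {genotype_freqs}")
    m = p1 + 2.0 * p2
    return (-m, 1.0 - m, 2.0 - m)


def noia_dominance_coding(
    genotype_freqs: tuple[float, float, float], eps: float = 1e-12
) -> tuple[float, float, float]:
    """Dominance codes for dosages (0, 1, 2), orthogonal to the additive codes
    under the observed genotype frequencies.

    Returns (-2*p1*p2/den, 4*p0*p2/den, -2*p0*p1/den) with
    den = p0 + p2 - (p0 - p2)**2.
    """
    p0, p1, p2 = genotype_freqs
    den = p0 + p2 - (p0 - p2) ** 2
    if den <= eps:
        raise DegenerateSNPError(
            f"degenerate dominance denominator {den:.3g} for genotype freqs "
            f"{genotype_freqs}"
        )
    return (-2.0 * p1 * p2 / den, 4.0 * p0 * p2 / den, -2.0 * p0 * p1 / den)


@dataclass
class CodingMatrices:
    """Per-SNP NOIA coding columns for an animal set.

    SNPs with no valid additive coding (monomorphic) are dropped from both
    matrices; SNPs with a degenerate dominance denominator are dropped from
    ``W_dom`` only, since their additive information is still valid.
    """

    W_add: np.ndarray
    W_dom: np.ndarray
    add_snp_ids: list[str]
    dom_snp_ids: list[str]
    excluded_snps: dict[str, str] = field(default_factory=dict)


def build_codings(g: GenotypeMatrix, eps: float = 1e-12) -> CodingMatrices:
    """Build NOIA coding matrices from observed genotype frequencies of ``g``."""
    return build_codings_from(g, g, eps=eps)


def build_codings_from(
    g: GenotypeMatrix, freq_source: GenotypeMatrix, eps: float = 1e-12
) -> CodingMatrices:
    """Build codings for the animals of ``g`` using genotype frequencies
    observed in ``freq_source`` (same SNP panel; used when frequencies must be
    recomputed on a subsample but codings applied to all animals)."""
    if freq_source.snp_ids != g.snp_ids:
        raise ValueError("freq_source must cover the same SNP panel")
    freqs = freq_source.genotype_freqs
    n, m = g.dosages.shape
    add_cols, dom_cols = [], []
    add_ids, dom_ids = [], []
    excluded: dict[str, str] = {}
    for j in range(m):
        trip = tuple(freqs[j])
        try:
            a_codes = noia_additive_coding(trip)
        except DegenerateSNPError as exc:
            excluded[g.snp_ids[j]] = str(exc)
            continue
        add_cols.append(np.asarray(a_codes)[g.dosages[:, j]])
        add_ids.append(g.snp_ids[j])
        try:
            d_codes = noia_dominance_coding(trip, eps=eps)
        except DegenerateSNPError as exc:
            excluded[g.snp_ids[j]] = str(exc)
            continue
        dom_cols.append(np.asarray(d_codes)[g.dosages[:, j]])
        dom_ids.append(g.snp_ids[j])
    if excluded:
        logger.info("excluded %d SNP(s) from coding matrices", len(excluded))
    W_add = np.stack(add_cols, axis=1) if add_cols else np.empty((n, 0))
    W_dom = np.stack(dom_cols, axis=1) if dom_cols else np.empty((n, 0))
    return CodingMatrices(W_add, W_dom, add_ids, dom_ids, excluded)


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------


@dataclass
class Kernel:
    name: str
    matrix: np.ndarray
    animal_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.animal_ids)
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"kernel {self.name}: matrix shape {self.matrix.shape} does not "
                f"match {n} animal IDs"
            )

    @property
    def n(self) -> int:
        return len(self.animal_ids)


class KernelSet(dict):
    """Ordered name -> Kernel map over one shared animal index."""

    def __init__(self, kernels: dict[str, Kernel] | None = None):
        super().__init__()
        if kernels:
            for name, k in kernels.items():
                self[name] = k

    def __setitem__(self, name: str, kernel: Kernel) -> None:
        if len(self):
            ref = next(iter(self.values()))
            _check_same_index(ref, kernel)
        super().__setitem__(name, kernel)

    @property
    def animal_ids(self) -> list[str]:
        return next(iter(self.values())).animal_ids


def _check_same_index(k1: Kernel, k2: Kernel) -> None:
    if k1.animal_ids != k2.animal_ids:
        for a, b in zip(k1.animal_ids, k2.animal_ids):
            if a != b:
                raise ValueError(
                    f"kernel animal indices differ: {a!r} vs {b!r}"
                )
        raise ValueError("kernel animal indices differ in length")


def scale_trace(matrix: np.ndarray) -> np.ndarray:
    """Rescale a symmetric matrix so its trace equals its dimension."""
    matrix = np.asarray(matrix, dtype=float)
    tr = np.trace(matrix)
    if tr <= 0:
        raise ValueError(f"cannot trace-scale matrix with trace {tr:.3g} <= 0")
    return matrix * (matrix.shape[0] / tr)


def build_kernel(W: np.ndarray, name: str, animal_ids: list[str]) -> Kernel:
    """Trace-scaled cross-product kernel from a coding matrix."""
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[1] < 1:
        raise ValueError(f"kernel {name}: coding matrix has no retained SNPs")
    K = W @ W.T
    return Kernel(name, scale_trace(K), animal_ids)


def hadamard_kernel(k1: Kernel, k2: Kernel, name: str) -> Kernel:
    """Element-wise product of two kernels, then trace-scaled."""
    _check_same_index(k1, k2)
    return Kernel(name, scale_trace(k1.matrix * k2.matrix), k1.animal_ids)


def exact_pairwise_aa(
    W_add: np.ndarray, animal_ids: list[str], scaled: bool = True
) -> Kernel:
    """Additive-by-additive kernel summed over unordered SNP pairs j < k only.

    Unlike the Hadamard product of A with itself, this excludes the squared
    same-SNP terms and counts each SNP pair once:
    ((WW') ⊙ (WW') − (W⊙W)(W⊙W)') / 2.
    """
    W = np.asarray(W_add, dtype=float)
    if W.shape[1] < 2:
        raise ValueError("exact pairwise AA requires at least 2 SNPs")
    WWt = W @ W.T
    W2 = W * W
    K = 0.5 * (WWt * WWt - W2 @ W2.T)
    if scaled:
        K = scale_trace(K)
    return Kernel("AA_exact", K, animal_ids)


def build_kernel_set(
    g: GenotypeMatrix,
    which: tuple[str, ...] = ("A", "D", "AA", "AD", "DD"),
    freq_source: GenotypeMatrix | None = None,
) -> KernelSet:
    """Build the requested relationship matrices from genotypes.

    Epistatic kernels are Hadamard products of the (already trace-scaled)
    A and D kernels, trace-scaled again after the product.
    """
    codings = build_codings_from(g, freq_source if freq_source is not None else g)
    ks = KernelSet()
    need_a = any(w in which for w in ("A", "AA", "AD"))
    need_d = any(w in which for w in ("D", "AD", "DD"))
    A = build_kernel(codings.W_add, "A", g.animal_ids) if need_a else None
    D = build_kernel(codings.W_dom, "D", g.animal_ids) if need_d else None
    parents = {"A": A, "D": D}
    for name in which:
        if name in ("A", "D"):
            ks[name] = parents[name]
        elif name in EPISTATIC_PARENTS:
            p1, p2 = EPISTATIC_PARENTS[name]
            ks[name] = hadamard_kernel(parents[p1], parents[p2], name)
        else:
            raise ValueError(f"unknown kernel name {name!r}")
    return ks


# ---------------------------------------------------------------------------
# SNP density reduction and LD summaries
# ---------------------------------------------------------------------------


def reduce_snp_density(
    g: GenotypeMatrix, fraction: float, block: int = 8, seed: int = 0
) -> GenotypeMatrix:
    """Thin the panel to a fraction of its density, sampling within
    consecutive blocks of ``block`` SNPs in genome order."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    per_block = fraction * block
    if abs(per_block - round(per_block)) > 1e-9:
        logger.warning(
            "fraction * block = %.3f is not integral; rounding to %d",
            per_block,
            round(per_block),
        )
    per_block = int(round(per_block))
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for start in range(0, g.n_snps, block):
        idx = np.arange(start, min(start + block, g.n_snps))
        k = per_block if idx.size == block else int(round(fraction * idx.size))
        k = min(k, idx.size)
        if k:
            keep.extend(sorted(rng.choice(idx, size=k, replace=False)))
    return g.subset_snps(np.asarray(keep, dtype=int))


def ld_adjacent_r2(
    g: GenotypeMatrix, quantiles: tuple[float, ...] = (0.5, 0.7, 0.9)
) -> dict:
    """Squared Pearson correlation of dosages for adjacent SNP pairs.

    Adjacency follows genome order within chromosome when positions are
    available, otherwise column order. Pairs with a zero-variance member are
    skipped and counted.
    """
    if g.n_snps < 2:
        raise ValueError("need at least 2 SNPs for adjacent-pair LD")
    X = g.dosages.astype(float)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    if g.positions is not None:
        chroms = np.asarray([c for c, _ in g.positions])
        order = np.lexsort((np.asarray([p for _, p in g.positions]), chroms))
        same_chrom = chroms[order][:-1] == chroms[order][1:]
        left, right = order[:-1][same_chrom], order[1:][same_chrom]
    else:
        left, right = np.arange(g.n_snps - 1), np.arange(1, g.n_snps)
    ok = (sd[left] > 0) & (sd[right] > 0)
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.warning("skipped %d adjacent pair(s) with zero variance", n_skipped)
    left, right = left[ok], right[ok]
    r = (X[:, left] * X[:, right]).mean(axis=0) / (sd[left] * sd[right])
    r2 = r**2
    return {
        "r2": r2,
        "quantiles": {q: float(np.quantile(r2, q)) for q in quantiles},
        "n_pairs": int(r2.size),
        "n_skipped": n_skipped,
    }


def offdiagonal_summary(
    kernels: KernelSet, quantiles: tuple[float, ...] = (0.05, 0.25, 0.5, 0.75, 0.95)
) -> dict[str, dict]:
    """Distribution statistics of strictly off-diagonal kernel entries."""
    out: dict[str, dict] = {}
    for name, k in kernels.items():
        if k.n < 2:
            raise ValueError("off-diagonal summary needs at least 2 animals")
        off = k.matrix[~np.eye(k.n, dtype=bool)]
        out[name] = {
            "mean": float(off.mean()),
            "sd": float(off.std()),
            "mean_abs": float(np.abs(off).mean()),
            "quantiles": {q: float(np.quantile(off, q)) for q in quantiles},
        }
    return out


# ---------------------------------------------------------------------------
# Text serialization: first row = animal IDs, then one row per animal with
# its ID followed by n tab-separated values at 12 significant digits.
# ---------------------------------------------------------------------------


def write_kernel(k: Kernel, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(k.animal_ids) + "\n")
        for i, aid in enumerate(k.animal_ids):
            vals = "\t".join(f"{v:.12g}" for v in k.matrix[i])
            fh.write(f"{aid}\t{vals}\n")


def read_kernel(path, name: str | None = None) -> Kernel:
    with open(path) as fh:
        ids = fh.readline().rstrip("\n").split("\t")
        rows = []
        row_ids = []
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            row_ids.append(fields[0])
            rows.append([float(v) for v in fields[1:]])
    if row_ids != ids:
        raise ValueError("kernel file row IDs do not match header IDs")
    return Kernel(name or "K", np.asarray(rows), ids)
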