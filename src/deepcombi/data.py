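"""Core GWAS data containers, one-hot encoding, standardization and TSV I/O.

Genotypes are stored as minor-allele counts (0/1/2) in an ``n x d`` integer
matrix with per-SNP metadata; phenotypes are binary labels (0 = control,
1 = case). The classifier stages operate on a one-hot expansion in which each
SNP contributes three indicator columns, one per count level, in the fixed
order (0, 1, 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SnpMeta:
    """Identity of one SNP: rs-style identifier, chromosome and 1-based position."""

    identifier: str
    chromosome: str
    position: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")


@dataclass
class GenotypeMatrix:
    """``n x d`` minor-allele counts with SNP metadata.

    Entries must lie in {0, 1, 2}; missing genotypes are rejected (upstream
    quality control is assumed to have removed or imputed them).
    """

    counts: np.ndarray
    snps: list[SnpMeta]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix (subjects x SNPs)")
        bad = ~np.isin(self.counts, (0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"genotype counts must be in {{0,1,2}}; found {self.counts[i, j]!r} "
                f"at subject {i}, SNP {j}"
            )
        self.counts = self.counts.astype(np.int8)
        if len(self.snps) != self.counts.shape[1]:
            raise ValueError("snps metadata length must equal the number of columns")
        ids = [s.identifier for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("SNP identifiers must be unique within a dataset")

    @property
    def n_subjects(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        """Column subset (boolean mask or index array), metadata included."""
        idx = np.flatnonzero(mask) if np.asarray(mask).dtype == bool else np.asarray(mask)
        return GenotypeMatrix(self.counts[:, idx], [self.snps[j] for j in idx])


def default_snp_meta(d: int, chromosome: str = "1") -> list[SnpMeta]:
    """Placeholder metadata snp_1..snp_d at consecutive positions."""
    return [SnpMeta(f"snp_{j + 1}", chromosome, j + 1) for j in range(d)]


@dataclass
class PhenotypeVector:
    """Binary case/control labels, 0 = control and 1 = case."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.isin(self.labels, (0, 1)).all():
            bad = self.labels[~np.isin(self.labels, (0, 1))][0]
            raise ValueError(f"phenotype labels must be 0/1, found {bad!r}")
        self.labels = self.labels.astype(np.int8)

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    def both_classes_present(self) -> bool:
        return bool((self.labels == 0).any() and (self.labels == 1).any())


@dataclass
class OneHotGenotypes:
    """``n x 3d`` indicator expansion; column triplet order is count (0, 1, 2)."""

    features: np.ndarray

    @property
    def n_snps(self) -> int:
        return self.features.shape[1] // 3


@dataclass(frozen=True)
class StandardizationStats:
    """Global scalar mean/std of a (training) one-hot matrix."""

    mean: float
    std: float

    def __post_init__(self) -> None:
        if not self.std > 0:
            raise ValueError("standard deviation must be positive")


@dataclass(frozen=True)
class SplitAssignment:
    """Stratified train/test partition of subjects."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    fraction: float


def encode_one_hot(g: GenotypeMatrix | np.ndarray) -> OneHotGenotypes:
    """Expand minor-allele counts into per-SNP indicator triplets.

    Count 0 -> (1,0,0), 1 -> (0,1,0), 2 -> (0,0,1).
    """
    counts = g.counts if isinstance(g, GenotypeMatrix) else np.asarray(g)
    bad = ~np.isin(counts, (0, 1, 2))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(f"count {counts[i, j]!r} at subject {i}, SNP {j} not in {{0,1,2}}")
    n, d = counts.shape
    features = np.zeros((n, 3 * d), dtype=np.float32)
    cols = 3 * np.arange(d)[None, :] + counts
    features[np.arange(n)[:, None], cols] = 1.0
    return OneHotGenotypes(features)


def decode_one_hot(x: OneHotGenotypes) -> np.ndarray:
    """Invert :func:`encode_one_hot` back to the count matrix."""
    n, w = x.features.shape
    if w % 3:
        raise ValueError("feature width must be a multiple of 3")
    return np.argmax(x.features.reshape(n, w // 3, 3), axis=2).astype(np.int8)


def standardize(
    x: OneHotGenotypes | np.ndarray,
    stats: StandardizationStats | None = None,
) -> tuple[np.ndarray, StandardizationStats]:
    """Center and scale by the global scalar mean/std of the whole matrix.

    When ``stats`` is None they are computed from ``x`` (the training matrix)
    and returned for reuse on held-out data.
    """
    features = x.features if isinstance(x, OneHotGenotypes) else np.asarray(x)
    if stats is None:
        mean = float(features.mean())
        std = float(features.std())
        if std == 0:
            raise ValueError("constant matrix: global standard deviation is zero")
        stats = StandardizationStats(mean, std)
    out = (features.astype(np.float64) - stats.mean) / stats.std
    return out, stats


def unstandardize(z: np.ndarray, stats: StandardizationStats) -> np.ndarray:
    return z * stats.std + stats.mean


def stratified_split(
    y: PhenotypeVector, fraction: float = 0.8, seed: int = 0
) -> SplitAssignment:
    """Class-balanced random train/test partition.

    Per class, ``round(fraction * n_class)`` subjects go to training, which
    keeps the class proportions of each part within one subject of the global
    proportion. Deterministic under a fixed seed.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(y.labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls} has fewer than 2 members; cannot split")
        rng.shuffle(idx)
        n_train = int(round(fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)  # both parts non-empty per class
        train_parts.append(idx[:n_train])
        test_parts.append(idx[n_train:])
    return SplitAssignment(
        np.sort(np.concatenate(train_parts)),
        np.sort(np.concatenate(test_parts)),
        fraction,
    )


# ---------------------------------------------------------------------------
# Text formats
#
# Genotype TSV: header  id<TAB>chrom<TAB>pos<TAB>subj_1...subj_n, one row per
# SNP, genotype cells in {0,1,2}.  Phenotype TSV: subject<TAB>label.  Results
# TSV: id chrom pos pvalue relevance selected significant.
# ---------------------------------------------------------------------------


def write_genotypes(path, g: GenotypeMatrix, y: PhenotypeVector | None = None) -> None:
    """Write the genotype TSV (and, if given, the phenotype TSV at path + '.pheno')."""
    n = g.n_subjects
    cols = {"id": [s.identifier for s in g.snps],
            "chrom": [s.chromosome for s in g.snps],
            "pos": [s.position for s in g.snps]}
    df = pd.DataFrame(cols)
    geno = pd.DataFrame(g.counts.T, columns=[f"subj_{i + 1}" for i in range(n)])
    pd.concat([df, geno], axis=1).to_csv(path, sep="\t", index=False)
    if y is not None:
        write_phenotypes(str(path) + ".pheno", y)


def write_phenotypes(path, y: PhenotypeVector) -> None:
    pd.DataFrame(
        {"subject": [f"subj_{i + 1}" for i in range(y.n)], "label": y.labels}
    ).to_csv(path, sep="\t", index=False)


def read_genotypes(path) -> GenotypeMatrix:
    """Read the genotype TSV; malformed rows are reported with their line number."""
    df = pd.read_csv(path, sep="\t")
    required = ["id", "chrom", "pos"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"{path}: expected header starting with {required}")
    geno = df.iloc[:, 3:].to_numpy()
    bad = ~np.isin(geno, (0, 1, 2))
    if bad.any():
        row = int(np.argwhere(bad)[0][0])
        raise ValueError(
            f"{path}: line {row + 2}: genotype value {geno[bad][0]!r} not in {{0,1,2}}"
        )
    dup = df["id"][df["id"].duplicated()]
    if len(dup):
        line = int(dup.index[0]) + 2
        raise ValueError(f"{path}: line {line}: duplicated SNP id {dup.iloc[0]!r}")
    snps = [
        SnpMeta(str(r.id), str(r.chrom), int(r.pos)) for r in df.itertuples(index=False)
    ]
    return GenotypeMatrix(geno.T, snps)


def read_phenotypes(path) -> PhenotypeVector:
    df = pd.read_csv(path, sep="\t")
    labels = df["label"].to_numpy()
    bad = ~np.isin(labels, (0, 1))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(f"{path}: line {row + 2}: phenotype {labels[row]!r} not in {{0,1}}")
    return PhenotypeVector(labels)


def write_results(path, g: GenotypeMatrix, result, relevance=None) -> None:
    """One row per SNP: p-value, relevance, selected and significant flags."""
    rel = np.zeros(g.n_snps) if relevance is None else np.asarray(relevance, dtype=float)
    df = pd.DataFrame(
        {
            "id": [s.identifier for s in g.snps],
            "chrom": [s.chromosome for s in g.snps],
            "pos": [s.position for s in g.snps],
            "pvalue": [f"{p:.6e}" for p in result.pvalues],
            "relevance": rel,
            "selected": result.selected.astype(int),
            "significant": result.significant.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
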