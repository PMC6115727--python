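"""Synthetic expression data with the generative structure the method assumes.

The generator emulates a bulk expression matrix that is the exact sum of
three parts: a low-rank background shared by all samples, a column-block
structured sparse component carrying subtype-specific signal (near zero for
normal samples), and per-entry Gaussian noise.  Ground truth (the three
components, the sparse support, subtype labels) is returned alongside the
matrix so recovery can be measured.

Subtype sample columns are laid out contiguously so that the left/right
neighbour structure assumed by the Markov sparsity prior is meaningful; a
shuffle option exists to stress-test that assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import NORMAL, TUMOR, ExpressionMatrix


@dataclass
class SyntheticSpec:
    """Parameters of the planted-structure generator.

    The defaults define the package's standard benchmark: P=200 genes,
    N=50 samples (4 tumor subtypes of 10 plus 10 normals), a rank-2
    background, per-subtype sparse blocks on 5% of genes at amplitude 10,
    and Gaussian noise with standard deviation 0.1.

    ``normal_amplitude`` sets the strength of a weak coherent signature on
    the normal samples' own support genes ("near-zero" relative to the tumor
    blocks).  The default of 0 plants strictly zero sparse columns for
    normal samples.
    """

    n_genes: int = 200
    n_samples: int = 50
    true_rank: int = 2
    n_subtypes: int = 4
    samples_per_subtype: int = 10
    n_normal: int = 10
    sparse_fraction: float = 0.05
    sparse_amplitude: float = 10.0
    normal_amplitude: float = 0.0
    noise_sd: float = 0.1
    seed: int = 0
    shuffle_columns: bool = False

    def validate(self) -> None:
        if min(self.n_genes, self.n_samples, self.true_rank, self.n_subtypes,
               self.samples_per_subtype) < 1 or self.n_normal < 0:
            raise ValueError("all counts must be positive")
        if self.n_subtypes * self.samples_per_subtype + self.n_normal != self.n_samples:
            raise ValueError(
                "n_subtypes * samples_per_subtype + n_normal must equal n_samples "
                f"({self.n_subtypes}*{self.samples_per_subtype}+{self.n_normal} != {self.n_samples})"
            )
        if not 0.0 < self.sparse_fraction < 1.0:
            raise ValueError("sparse_fraction must lie in (0, 1)")
        n_support = int(round(self.sparse_fraction * self.n_genes))
        n_groups = self.n_subtypes + (1 if self.n_normal else 0)
        if n_support * n_groups > self.n_genes:
            raise ValueError("disjoint supports do not fit: lower sparse_fraction")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a generated matrix."""

    L0: np.ndarray
    S0: np.ndarray
    E0: np.ndarray
    support: np.ndarray            # boolean P x N, support of S0
    subtype_labels: np.ndarray     # per sample: "S1".."Sk" or "normal"
    is_normal: np.ndarray          # boolean per sample
    informative_genes: np.ndarray  # sorted row indices in the sparse support
    column_order: np.ndarray = field(default=None)  # type: ignore[assignment]


def generate_dataset(spec: SyntheticSpec) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw one dataset ``Y = L0 + S0 + E0`` with planted subtype structure.

    The low-rank part is a product of standard Gaussian factors; each tumor
    subtype has its own (disjoint) support of ``round(sparse_fraction * P)``
    genes carrying a constant positive amplitude in that subtype's
    contiguous sample columns; normal samples carry either exactly zero
    sparse signal (default) or a weak signature on their own support.
    Deterministic for a fixed ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    P, N, r = spec.n_genes, spec.n_samples, spec.true_rank

    L0 = rng.standard_normal((P, r)) @ rng.standard_normal((r, N))

    n_support = int(round(spec.sparse_fraction * P))
    n_groups = spec.n_subtypes + (1 if spec.n_normal else 0)
    support_pool = rng.choice(P, size=n_support * n_groups, replace=False)

    S0 = np.zeros((P, N))
    support = np.zeros((P, N), dtype=bool)
    labels = []
    col = 0
    for k in range(spec.n_subtypes):
        genes = support_pool[k * n_support:(k + 1) * n_support]
        cols = np.arange(col, col + spec.samples_per_subtype)
        S0[np.ix_(genes, cols)] = spec.sparse_amplitude
        support[np.ix_(genes, cols)] = True
        labels += [f"S{k + 1}"] * spec.samples_per_subtype
        col += spec.samples_per_subtype
    if spec.n_normal:
        cols = np.arange(col, col + spec.n_normal)
        if spec.normal_amplitude != 0.0:
            genes = support_pool[spec.n_subtypes * n_support:]
            S0[np.ix_(genes, cols)] = spec.normal_amplitude
            support[np.ix_(genes, cols)] = True
        labels += [NORMAL] * spec.n_normal

    E0 = rng.standard_normal((P, N)) * spec.noise_sd

    order = np.arange(N)
    if spec.shuffle_columns:
        order = rng.permutation(N)
        L0, S0, E0, support = L0[:, order], S0[:, order], E0[:, order], support[:, order]
        labels = [labels[i] for i in order]

    labels = np.asarray(labels, dtype=object)
    is_normal = labels == NORMAL
    Y = L0 + S0 + E0
    em = ExpressionMatrix(
        values=Y,
        gene_ids=[f"g{p:04d}" for p in range(P)],
        sample_ids=[f"s{n:03d}" for n in range(N)],
        group=np.where(is_normal, NORMAL, TUMOR),
    )
    truth = SyntheticTruth(
        L0=L0, S0=S0, E0=E0, support=support,
        subtype_labels=labels, is_normal=is_normal,
        informative_genes=np.sort(np.unique(np.nonzero(support)[0])),
        column_order=order,
    )
    return em, truth


def correlated_blocks(n_per_block: list[int], block_corr: float, n_genes: int = 100,
                      cross_corr: float = 0.0, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Columns with planted block correlation, for clustering benchmarks.

    Each column is ``sqrt(c) * f_block + sqrt(1 - c) * noise`` with a shared
    per-block factor, giving within-block correlation ``c`` and cross-block
    correlation ``cross_corr`` (via a global factor) in expectation.

    Returns the ``n_genes x sum(n_per_block)`` matrix and integer block
    labels per column.
    """
    if not 0.0 <= cross_corr <= block_corr <= 1.0:
        raise ValueError("need 0 <= cross_corr <= block_corr <= 1")
    rng = np.random.default_rng(seed)
    cols, labels = [], []
    g = rng.standard_normal(n_genes)
    for b, n in enumerate(n_per_block):
        f = rng.standard_normal(n_genes)
        for _ in range(n):
            eps = rng.standard_normal(n_genes)
            x = (np.sqrt(cross_corr) * g
                 + np.sqrt(block_corr - cross_corr) * f
                 + np.sqrt(1.0 - block_corr) * eps)
            cols.append(x)
            labels.append(b)
    return np.column_stack(cols), np.asarray(labels)
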