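"""Forward-model simulator with ground truth for batch-correction benchmarks.

Observed expression follows the additive/multiplicative location-scale model

    Y_ijk = (X beta_x)_jk + alpha_k + gamma_ik + delta_ik * eps_ijk,

where i indexes batches, j samples and k genes.  The biological design X is
a set of binary categorical features; each distinct feature row defines a
Zero-Hop (a group of samples sharing the exact experimental design).  Batch
effects are an additive shift gamma_ik ~ Normal(gamma_bar_i, sd^2) with
batch-level means gamma_bar_i ~ Normal(0, sd^2), and a multiplicative scale
delta_ik^2 ~ InverseGamma(shape, scale) — the same families the parametric
empirical-Bayes correction assumes, so parameter recovery is well-posed.

The ground-truth matrix keeps the noise term (X beta_x + alpha + eps):
perfect correction means agreeing with the noisy batch-free data, not
impossible denoising.  Setting ``additive_batch_sd=0`` switches additive
effects off exactly; ``multiplicative_scale=0`` pins delta^2 = 1 exactly.

Default sizes mirror a moderately hard integration problem: 500 samples in
10 batches, 10 Zero-Hops over 5 binary design features, 200 genes,
batch-shift SD 2 against unit observation noise.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .data_io import ExpressionMatrix, SampleMetadata, write_expression
from .design import DesignSpec, zero_hops

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate", "write_dataset"]


@dataclass
class SimulationConfig:
    """Generation hyperparameters; a single seed drives all randomness.

    ``disturbance_ratio`` scales the biological design effects relative to
    the additive batch-effect SD (the relative disturbance size of metadata
    to batch).  ``singular_design`` duplicates one design feature under a
    second name, which makes the full one-hot encoded design rank-deficient.
    """

    n_samples: int = 500
    n_batches: int = 10
    n_design_features: int = 5
    n_zero_hops: int = 10
    n_genes: int = 200
    disturbance_ratio: float = 1.0
    additive_batch_sd: float = 2.0
    multiplicative_shape: float = 4.0
    multiplicative_scale: float = 3.0
    noise_sd: float = 1.0
    singular_design: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_genes < 1:
            raise ValueError("n_samples and n_genes must be positive")
        if self.n_batches < 1:
            raise ValueError("need at least one batch")
        if self.n_zero_hops < 1:
            raise ValueError("need at least one Zero-Hop")
        if self.n_zero_hops > 2**self.n_design_features:
            raise ValueError(
                f"{self.n_zero_hops} Zero-Hops need more than "
                f"2^{self.n_design_features} distinct binary design rows"
            )
        if self.n_samples < max(self.n_batches, self.n_zero_hops):
            raise ValueError(
                "every batch and every Zero-Hop must receive at least one sample"
            )
        for name in (
            "disturbance_ratio",
            "additive_batch_sd",
            "multiplicative_shape",
            "multiplicative_scale",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SimulatedDataset:
    observed: ExpressionMatrix
    ground_truth: ExpressionMatrix
    metadata: SampleMetadata
    zero_hop_labels: list[str]
    true_gamma: np.ndarray
    true_delta_sq: np.ndarray
    true_beta_x: np.ndarray
    true_alpha: np.ndarray
    batch_names: list[str]
    config: SimulationConfig

    @property
    def batch_labels(self) -> list[str]:
        return self.metadata.batch_labels

    def design_spec(self) -> DesignSpec:
        """The DesignSpec matching the generated metadata columns."""
        desired = [f"f{i}" for i in range(self.config.n_design_features)]
        if self.config.singular_design:
            desired.append("f0_dup")
        return DesignSpec(batch_column="batch", desired_columns=desired)


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Draw one dataset from the forward model; bit-reproducible per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, g = config.n_samples, config.n_genes
    nb, nf, nz = config.n_batches, config.n_design_features, config.n_zero_hops

    # distinct binary design rows, one per Zero-Hop
    rows: dict[tuple, None] = {}
    while len(rows) < nz:
        rows[tuple(rng.integers(0, 2, size=nf))] = None
    hop_rows = np.array(list(rows.keys()), dtype=float)

    # balanced Zero-Hop assignment, then shuffled
    hop_of = np.tile(np.arange(nz), n // nz + 1)[:n]
    rng.shuffle(hop_of)

    # random batch assignment guaranteeing minimum counts (2 when feasible,
    # else 1) so downstream variance estimates are defined
    min_per_batch = 2 if n >= 2 * nb else 1
    batch_of = np.tile(np.arange(nb), min_per_batch)
    batch_of = np.concatenate([batch_of, rng.integers(0, nb, size=n - len(batch_of))])
    rng.shuffle(batch_of)

    X = hop_rows[hop_of]  # n x nf binary design
    s_x = config.disturbance_ratio * config.additive_batch_sd
    beta_x = rng.normal(0.0, s_x, size=(nf, g)) if s_x > 0 else np.zeros((nf, g))
    alpha = rng.normal(0.0, 1.0, size=g)

    sd = config.additive_batch_sd
    gamma_bar = rng.normal(0.0, sd, size=nb) if sd > 0 else np.zeros(nb)
    gamma = (
        rng.normal(gamma_bar[:, None], sd, size=(nb, g)) if sd > 0 else np.zeros((nb, g))
    )
    if config.multiplicative_scale == 0:
        delta_sq = np.ones((nb, g))
    else:
        # InverseGamma(shape, scale) = scale / Gamma(shape, 1)
        delta_sq = config.multiplicative_scale / rng.gamma(
            config.multiplicative_shape, 1.0, size=(nb, g)
        )
    eps = rng.normal(0.0, config.noise_sd, size=(n, g))

    signal = X @ beta_x + alpha[None, :]
    ground_truth = signal + eps
    observed = signal + gamma[batch_of] + np.sqrt(delta_sq)[batch_of] * eps

    width = max(4, len(str(n - 1)))
    sample_ids = [f"s{j:0{width}d}" for j in range(n)]
    gene_ids = [f"g{k:0{max(4, len(str(g - 1)))}d}" for k in range(g)]
    batch_names = [f"b{i:02d}" for i in range(nb)]

    columns: dict[str, list] = {"batch": [batch_names[i] for i in batch_of]}
    for f in range(nf):
        columns[f"f{f}"] = [str(int(v)) for v in X[:, f]]
    if config.singular_design:
        columns["f0_dup"] = list(columns["f0"])
    meta = SampleMetadata(sample_ids=sample_ids, columns=columns, batch_column="batch")

    ds = SimulatedDataset(
        observed=ExpressionMatrix(observed, sample_ids, gene_ids),
        ground_truth=ExpressionMatrix(ground_truth, list(sample_ids), list(gene_ids)),
        metadata=meta,
        zero_hop_labels=[],
        true_gamma=gamma,
        true_delta_sq=delta_sq,
        true_beta_x=beta_x,
        true_alpha=alpha,
        batch_names=batch_names,
        config=config,
    )
    ds.zero_hop_labels = zero_hops(meta, ds.design_spec())
    return ds


def write_dataset(ds: SimulatedDataset, prefix) -> None:
    """Write observed/truth matrices, metadata CSV and a true-parameter JSON."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    write_expression(ds.observed, f"{prefix}_observed.csv")
    write_expression(ds.ground_truth, f"{prefix}_truth.csv")
    ds.metadata.to_frame().to_csv(f"{prefix}_metadata.csv", index_label="sample")
    params = {
        "config": asdict(ds.config),
        "batch_names": ds.batch_names,
        "true_gamma": ds.true_gamma.tolist(),
        "true_delta_sq": ds.true_delta_sq.tolist(),
        "true_beta_x": ds.true_beta_x.tolist(),
        "true_alpha": ds.true_alpha.tolist(),
        "zero_hop_labels": ds.zero_hop_labels,
    }
    with open(f"{prefix}_params.json", "w") as fh:
        json.dump(params, fh)
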