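"""Synthetic probe-level two-channel microarray data with planted effects.

The generative model mirrors the assumptions of the downstream preprocessing:

- each probe has a baseline abundance drawn from an exponential distribution
  (so observed intensity = normal optical background + exponential signal,
  the model behind normexp background correction);
- every test sample is "labelled Cy3" and hybridised against a Cy5 common
  reference that is the pooled mean of all test-sample signals;
- the test channel carries, in log2-ratio space: the planted temporal
  profile of its gene, a per-slide batch offset, an intensity-dependent dye
  bias (polynomial in the mean log2 intensity A), and Gaussian noise.

The design is the study's: two cell lines (control "C" and disease "HD"),
nine time points (0 = pre-induction, 4 ... 120 h), six replicates each, i.e.
108 test arrays hybridised across nine slides of twelve arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProfileSpec",
    "ArraySimConfig",
    "ArrayGroundTruth",
    "gen_array_data",
    "sample_normexp",
    "make_planted_profiles",
]

TIMEPOINTS_H = (0, 4, 8, 24, 36, 48, 72, 96, 120)
CELL_LINES = ("C", "HD")


@dataclass(frozen=True)
class ProfileSpec:
    """A planted temporal log2-fold-change profile.

    The profile is 0 up to ``onset_h``, ramps linearly to ``max_abs_log2fc``
    (signed by ``direction``) at ``peak_h`` and stays there.  ``shared=True``
    plants the same response in both cell lines (so the disease-specific
    double difference is zero); otherwise the response is specific to the
    disease line.
    """

    direction: str  # "up" | "down"
    onset_h: float
    peak_h: float
    max_abs_log2fc: float
    shared: bool = False

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if not 0 <= self.onset_h < self.peak_h:
            raise ValueError("need 0 <= onset_h < peak_h")

    def __call__(self, t: float) -> float:
        if t <= self.onset_h:
            return 0.0
        frac = min((t - self.onset_h) / (self.peak_h - self.onset_h), 1.0)
        sign = 1.0 if self.direction == "up" else -1.0
        return sign * self.max_abs_log2fc * frac


@dataclass(frozen=True)
class ArraySimConfig:
    """Configuration of the synthetic two-channel array experiment."""

    n_genes: int = 2000
    probes_per_gene: tuple[int, int] = (2, 4)  # inclusive range, drawn per gene
    timepoints: tuple[float, ...] = TIMEPOINTS_H
    replicates_per_condition: int = 6
    n_slides: int = 9
    arrays_per_slide: int = 12
    slide_effect_sd: float = 0.1  # log2 units
    dye_bias_coefficients: tuple[float, ...] = ()  # polynomial in A, highest first
    noise_sd: float = 0.2  # log2 units
    planted_profiles: dict[str, ProfileSpec] = field(default_factory=dict)
    background_mean: float = 100.0  # AFU
    background_sd: float = 15.0  # AFU
    signal_exp_mean: float = 1000.0  # AFU
    reference_noisy: bool = False
    seed: int = 0

    @property
    def n_arrays(self) -> int:
        return len(self.timepoints) * self.replicates_per_condition * len(CELL_LINES)

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be > 0")
        lo, hi = self.probes_per_gene
        if not 1 <= lo <= hi <= 4:
            raise ValueError("probes_per_gene must lie within 1..4")
        if 0.0 not in [float(t) for t in self.timepoints]:
            raise ValueError("the design requires the 0 h pre-induction time point")
        if self.n_slides * self.arrays_per_slide < self.n_arrays:
            raise ValueError(
                f"{self.n_arrays} arrays do not fit on {self.n_slides} slides "
                f"of {self.arrays_per_slide}"
            )


@dataclass
class ArrayGroundTruth:
    """Oracle for differential-expression tests.

    ``de_genes`` are genes with a planted disease-specific response;
    ``true_logfc`` is the gene x time point matrix of the true
    double-difference log2 fold change (HD_t - HD_0) - (C_t - C_0).
    Shared responses cancel there by construction.
    """

    de_genes: set[str]
    true_logfc: pd.DataFrame  # index gene_id, columns time_h
    shared_genes: set[str] = field(default_factory=set)


def sample_normexp(
    n: int, mu: float, sigma: float, alpha: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw observed intensities = N(mu, sigma^2) background + Exp(alpha) signal."""
    return rng.normal(mu, sigma, n) + rng.exponential(alpha, n)


def make_planted_profiles(
    n_genes: int,
    n_hd_specific: int,
    n_shared: int = 0,
    max_abs_log2fc: float = 1.0,
    onset_h: float = 8.0,
    peak_h: float = 72.0,
    rng: np.random.Generator | None = None,
) -> dict[str, ProfileSpec]:
    """Plant balanced up/down profiles on the first genes of the panel."""
    if n_hd_specific + n_shared > n_genes:
        raise ValueError("more planted genes than genes in the panel")
    rng = rng or np.random.default_rng(0)
    profiles: dict[str, ProfileSpec] = {}
    for i in range(n_hd_specific + n_shared):
        profiles[f"g{i:05d}"] = ProfileSpec(
            direction="up" if i % 2 == 0 else "down",
            onset_h=onset_h,
            peak_h=peak_h,
            max_abs_log2fc=max_abs_log2fc,
            shared=i >= n_hd_specific,
        )
    return profiles


def _array_layout(config: ArraySimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    i = 0
    for line in CELL_LINES:
        for t in config.timepoints:
            for rep in range(config.replicates_per_condition):
                rows.append(
                    {
                        "array_id": f"a{i:03d}",
                        "cellline": line,
                        "time_h": float(t),
                        "replicate": rep,
                    }
                )
                i += 1
    layout = pd.DataFrame(rows)
    # randomized hybridisation across slides
    slots = np.repeat(np.arange(config.n_slides), config.arrays_per_slide)[: len(layout)]
    layout["slide_id"] = [f"s{j}" for j in rng.permutation(slots)]
    return layout


def gen_array_data(config: ArraySimConfig) -> tuple[pd.DataFrame, ArrayGroundTruth]:
    """Simulate probe-level two-channel intensities plus ground truth.

    Returns a long-format table with columns ``probe_id, gene_id, array_id,
    slide_id, cellline, time_h, replicate, cy3, cy5``.
    """
    rng = np.random.default_rng(config.seed)
    layout = _array_layout(config, rng)
    n_arrays = len(layout)

    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    lo, hi = config.probes_per_gene
    n_probes_per_gene = rng.integers(lo, hi + 1, size=config.n_genes)
    gene_of_probe = np.repeat(np.arange(config.n_genes), n_probes_per_gene)
    n_probes = len(gene_of_probe)
    probe_ids = np.array([f"p{i:06d}" for i in range(n_probes)])

    base = rng.exponential(config.signal_exp_mean, n_probes)  # probe affinity, AFU

    # planted per-gene log2 profile evaluated per array
    mu = np.zeros((config.n_genes, n_arrays))
    for gi, g in enumerate(genes):
        spec = config.planted_profiles.get(g)
        if spec is None:
            continue
        for ai, row in layout.iterrows():
            if row.cellline == "HD" or spec.shared:
                mu[gi, ai] = spec(row.time_h)
    mu_probe = mu[gene_of_probe]  # probes x arrays

    slide_levels = sorted(layout["slide_id"].unique())
    slide_offsets = dict(
        zip(slide_levels, rng.normal(0.0, config.slide_effect_sd, len(slide_levels)))
    )
    delta = layout["slide_id"].map(slide_offsets).to_numpy()  # per array

    noise = (
        rng.normal(0.0, config.noise_sd, size=(n_probes, n_arrays))
        if config.noise_sd > 0
        else np.zeros((n_probes, n_arrays))
    )

    # pooled common reference: mean test signal of every probe across arrays
    test_signal_clean = base[:, None] * np.exp2(mu_probe)
    ref = test_signal_clean.mean(axis=1)

    m_extra = delta[None, :] + noise
    if config.dye_bias_coefficients:
        with np.errstate(divide="ignore"):
            a_clean = 0.5 * np.log2(
                np.maximum(test_signal_clean * ref[:, None], 1e-12)
            )
        m_extra = m_extra + np.polyval(config.dye_bias_coefficients, a_clean)

    cy3_signal = test_signal_clean * np.exp2(m_extra)
    cy5_signal = np.broadcast_to(ref[:, None], (n_probes, n_arrays))

    if config.background_sd > 0:
        bg3 = rng.normal(config.background_mean, config.background_sd, (n_probes, n_arrays))
        bg5 = (
            rng.normal(config.background_mean, config.background_sd, (n_probes, n_arrays))
            if config.reference_noisy
            else np.full((n_probes, n_arrays), config.background_mean)
        )
    else:
        bg3 = np.full((n_probes, n_arrays), config.background_mean)
        bg5 = np.full((n_probes, n_arrays), config.background_mean)

    cy3 = np.clip(bg3 + cy3_signal, 0.0, None)
    cy5 = np.clip(bg5 + cy5_signal, 0.0, None)

    long = pd.DataFrame(
        {
            "probe_id": np.repeat(probe_ids, n_arrays),
            "gene_id": np.repeat(np.array(genes)[gene_of_probe], n_arrays),
            "array_id": np.tile(layout["array_id"].to_numpy(), n_probes),
            "slide_id": np.tile(layout["slide_id"].to_numpy(), n_probes),
            "cellline": np.tile(layout["cellline"].to_numpy(), n_probes),
            "time_h": np.tile(layout["time_h"].to_numpy(), n_probes),
            "replicate": np.tile(layout["replicate"].to_numpy(), n_probes),
            "cy3": cy3.ravel(),
            "cy5": cy5.ravel(),
        }
    )

    times = [float(t) for t in config.timepoints]
    true_logfc = pd.DataFrame(0.0, index=genes, columns=times)
    de_genes: set[str] = set()
    shared_genes: set[str] = set()
    for g, spec in config.planted_profiles.items():
        if spec.shared:
            shared_genes.add(g)
            continue  # double difference cancels shared responses
        de_genes.add(g)
        for t in times:
            true_logfc.loc[g, t] = spec(t)
    return long, ArrayGroundTruth(
        de_genes=de_genes, true_logfc=true_logfc, shared_genes=shared_genes
    )
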