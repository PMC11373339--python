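"""Generative model of bottom-up proteomics peptide tables.

Emulates the statistical structure a peptide-level imputer exploits:

* peptides of the same protein share a protein base level and a
  protein-by-sample biological effect, so clique mates are correlated;
* each peptide carries a fixed ionization-efficiency offset and its own
  heteroscedastic residual noise level;
* a fraction of peptides is shared between two proteins (signal = mean of
  the parents), merging cliques into larger components;
* missingness is a union of MCAR dropout and abundance-dependent
  (logistic, left-censoring-like) MNAR dropout;
* optional two-condition spike-in designs with a known set of
  differentially abundant proteins;
* sequence embeddings that are informative but noisy: a linear map of the
  peptide's latent properties (offset, noise sd, protein base level) plus
  Gaussian noise.

Everything is driven by one seed and is reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datamodel import PeptideDataset, DataError

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "generate_dataset",
    "expected_clique_correlation",
    "make_benchmark_fixture",
    "preset_spec",
    "PRESETS",
]

_AA = "ACDEFGHIKLMNPQSTVWY"  # tryptic-like bodies; peptides end in K/R


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of the generative model.

    Abundances live on the natural-log scale internally; the emitted
    dataset is ``exp`` of them.  ``base_mean``/``base_sd`` are the protein
    base-level moments (sigma_0), ``protein_sd`` the protein-by-sample
    biological variation shared by clique mates, ``peptide_offset_sd`` the
    ionization-efficiency spread, and ``noise_sd_range`` the uniform range
    the per-peptide residual sd is drawn from.
    """

    n_proteins: int = 40
    peptides_per_protein: tuple = (4, 6)  # inclusive range
    shared_peptide_fraction: float = 0.05
    n_samples: int = 8
    n_conditions: int = 1
    de_fraction: float = 0.0
    de_log_effect: float = 1.0
    base_mean: float = 20.0
    base_sd: float = 1.0
    protein_sd: float = 0.6
    peptide_offset_sd: float = 0.3
    noise_sd_range: tuple = (0.1, 0.8)
    mcar_rate: float = 0.2
    mnar_threshold: float | None = None  # log-scale tau; None disables MNAR
    mnar_steepness: float = 0.3
    embedding_dim: int = 64
    embedding_noise: float = 0.3
    seed: int = 0

    def validate(self):
        if self.n_proteins < 1:
            raise DataError("need >= 1 protein")
        lo, hi = self.peptides_per_protein
        if not (1 <= lo <= hi):
            raise DataError("bad peptides_per_protein range")
        if not 0 <= self.shared_peptide_fraction < 1:
            raise DataError("shared_peptide_fraction must be in [0, 1)")
        if not 0 <= self.mcar_rate < 1:
            raise DataError("mcar_rate must be in [0, 1)")
        if self.n_conditions not in (1, 2):
            raise DataError("n_conditions must be 1 or 2")
        if self.n_conditions == 2 and self.n_samples < 4:
            raise DataError("two-condition designs need >= 4 samples")
        if self.noise_sd_range[0] < 0 or self.noise_sd_range[1] < self.noise_sd_range[0]:
            raise DataError("bad noise_sd_range")
        if self.mnar_steepness <= 0:
            raise DataError("mnar_steepness must be > 0")
        if self.seed is None:
            raise DataError("seed is mandatory")


@dataclass
class SyntheticTruth:
    """Ground-truth carrier aligned with the emitted dataset."""

    log_abundance: np.ndarray  # n x s complete matrix, pre-missingness (natural log)
    de_labels: np.ndarray  # n bool, True for peptides of DE proteins
    cause: np.ndarray  # n x s, 0 observed / 1 mcar / 2 mnar
    peptide_offsets: np.ndarray
    noise_sds: np.ndarray
    condition_of_sample: np.ndarray  # s int, condition index per sample

    CAUSE_OBSERVED = 0
    CAUSE_MCAR = 1
    CAUSE_MNAR = 2


def _random_peptide_sequence(rng: np.random.Generator) -> str:
    length = int(rng.integers(7, 21))
    body = "".join(rng.choice(list(_AA), size=length - 1))
    return body + ("K" if rng.random() < 0.5 else "R")


def generate_dataset(spec: SyntheticSpec):
    """Draw one dataset from the generative model.

    Returns ``(PeptideDataset, SyntheticTruth, embeddings)`` where
    ``embeddings`` is an ``n x embedding_dim`` float matrix whose rows are
    aligned with the dataset's peptides.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.peptides_per_protein
    ppp = rng.integers(lo, hi + 1, size=spec.n_proteins)
    n = int(ppp.sum())
    s = spec.n_samples

    # sample -> condition assignment (first half condition 0)
    cond = np.zeros(s, dtype=int)
    if spec.n_conditions == 2:
        cond[s // 2 :] = 1

    # protein-level signal: base level + per-sample biological effect + DE shift
    base = rng.normal(spec.base_mean, spec.base_sd, size=spec.n_proteins)
    u = rng.normal(0.0, spec.protein_sd, size=(spec.n_proteins, s))
    de_protein = np.zeros(spec.n_proteins, dtype=bool)
    delta = np.zeros(spec.n_proteins)
    if spec.n_conditions == 2 and spec.de_fraction > 0:
        n_de = max(1, int(round(spec.de_fraction * spec.n_proteins)))
        de_protein[rng.choice(spec.n_proteins, size=n_de, replace=False)] = True
        sign = rng.choice([-1.0, 1.0], size=spec.n_proteins)
        delta = np.where(de_protein, sign * spec.de_log_effect, 0.0)
    protein_signal = base[:, None] + u + delta[:, None] * (cond[None, :] == 1)

    # peptide membership: primary protein by block; a fraction gets a second parent
    primary = np.repeat(np.arange(spec.n_proteins), ppp)
    second = np.full(n, -1, dtype=int)
    if spec.shared_peptide_fraction > 0 and spec.n_proteins > 1:
        n_shared = int(np.floor(spec.shared_peptide_fraction * n))
        shared_idx = rng.choice(n, size=n_shared, replace=False)
        for i in shared_idx:
            other = int(rng.integers(spec.n_proteins - 1))
            if other >= primary[i]:
                other += 1
            second[i] = other

    offsets = rng.normal(0.0, spec.peptide_offset_sd, size=n)
    noise_sd = rng.uniform(*spec.noise_sd_range, size=n)

    signal = protein_signal[primary]
    shared = second >= 0
    if shared.any():
        signal[shared] = 0.5 * (signal[shared] + protein_signal[second[shared]])
    eps = rng.normal(0.0, 1.0, size=(n, s)) * noise_sd[:, None]
    y = signal + offsets[:, None] + eps

    # missingness: MCAR union MNAR; cause tie-break -> MCAR
    mcar = rng.random((n, s)) < spec.mcar_rate
    if spec.mnar_threshold is not None:
        p_mnar = 1.0 / (1.0 + np.exp(-(spec.mnar_threshold - y) / spec.mnar_steepness))
        mnar = rng.random((n, s)) < p_mnar
    else:
        mnar = np.zeros((n, s), dtype=bool)
    cause = np.zeros((n, s), dtype=np.int8)
    cause[mnar] = SyntheticTruth.CAUSE_MNAR
    cause[mcar] = SyntheticTruth.CAUSE_MCAR
    missing = mcar | mnar

    abundance = np.exp(y)
    abundance[missing] = np.nan

    peptide_ids = []
    seen: set = set()
    while len(peptide_ids) < n:
        seq = _random_peptide_sequence(rng)
        if seq not in seen:
            seen.add(seq)
            peptide_ids.append(seq)
    protein_groups = []
    for i in range(n):
        g = {f"P{primary[i]:05d}"}
        if second[i] >= 0:
            g.add(f"P{second[i]:05d}")
        protein_groups.append(frozenset(g))
    sample_ids = [f"S{j + 1:02d}" for j in range(s)]
    sample_groups = {sample_ids[j]: f"cond{cond[j] + 1}" for j in range(s)} if spec.n_conditions == 2 else None

    ds = PeptideDataset(
        abundance,
        peptide_ids,
        protein_groups,
        sample_ids,
        sample_groups=sample_groups,
        sequences=dict(zip(peptide_ids, peptide_ids)),
    )

    # embeddings: linear map of latent peptide properties + noise
    latent = np.column_stack([offsets, noise_sd, base[primary]])
    latent = (latent - latent.mean(axis=0)) / (latent.std(axis=0) + 1e-12)
    proj = rng.normal(0.0, 1.0, size=(latent.shape[1], spec.embedding_dim)) / np.sqrt(latent.shape[1])
    embeddings = latent @ proj + rng.normal(0.0, spec.embedding_noise, size=(n, spec.embedding_dim))

    de_labels = de_protein[primary].copy()
    if shared.any():
        de_labels[shared] |= de_protein[second[shared]]

    truth = SyntheticTruth(
        log_abundance=y,
        de_labels=de_labels,
        cause=cause,
        peptide_offsets=offsets,
        noise_sds=noise_sd,
        condition_of_sample=cond,
    )
    return ds, truth, embeddings


def expected_clique_correlation(spec: SyntheticSpec) -> float:
    """Population Pearson correlation between two same-protein peptides'
    abundance values over random (protein, sample) draws.

    Shared variance: protein base level (base_sd^2) plus protein-by-sample
    effect (protein_sd^2).  Individual variance adds the peptide offset and
    the mean residual variance E[sigma^2] = (hi^3 - lo^3) / (3 (hi - lo))
    for sigma ~ Uniform(lo, hi).
    """
    lo, hi = spec.noise_sd_range
    mean_noise_var = (hi**3 - lo**3) / (3 * (hi - lo)) if hi > lo else lo**2
    shared = spec.base_sd**2 + spec.protein_sd**2
    total = shared + spec.peptide_offset_sd**2 + mean_noise_var
    return shared / total


PRESETS: dict[str, SyntheticSpec] = {
    # ~200 peptides x 8 samples, one condition, mixed MCAR + mild MNAR
    "small": SyntheticSpec(
        n_proteins=40,
        peptides_per_protein=(4, 6),
        shared_peptide_fraction=0.05,
        n_samples=8,
        mcar_rate=0.20,
        mnar_threshold=18.6,
        mnar_steepness=0.4,
        seed=11,
    ),
    # ~2000 peptides x 12 samples, strong within-protein correlation, 30% MCAR
    "medium": SyntheticSpec(
        n_proteins=400,
        peptides_per_protein=(4, 6),
        shared_peptide_fraction=0.05,
        n_samples=12,
        base_sd=1.0,
        protein_sd=0.6,
        peptide_offset_sd=0.3,
        noise_sd_range=(0.1, 0.8),
        mcar_rate=0.30,
        mnar_threshold=None,
        seed=12,
    ),
    # two-condition spike-in design with 10% DE proteins and MNAR missingness
    "de_spikein": SyntheticSpec(
        n_proteins=150,
        peptides_per_protein=(4, 6),
        shared_peptide_fraction=0.05,
        n_samples=12,
        n_conditions=2,
        de_fraction=0.10,
        de_log_effect=1.2,
        mcar_rate=0.10,
        mnar_threshold=18.8,
        mnar_steepness=0.4,
        seed=13,
    ),
}


def make_benchmark_fixture(name: str, test_frac: float = 0.10, val_frac: float = 0.10):
    """Deterministic preset datasets used by the test suite and docs.

    Returns ``(dataset, truth, embeddings, MaskPlan)``; the mask plan uses
    the uniform masking mechanism with the preset's fixed seed.
    """
    from .datamodel import make_masked_split

    if name not in PRESETS:
        raise DataError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    spec = PRESETS[name]
    ds, truth, emb = generate_dataset(spec)
    plan = make_masked_split(ds, test_frac=test_frac, val_frac=val_frac, seed=spec.seed + 1000)
    return ds, truth, emb, plan


def preset_spec(name: str, seed: int | None = None) -> SyntheticSpec:
    """A preset's spec, optionally reseeded (for multi-seed experiments)."""
    if name not in PRESETS:
        raise DataError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    spec = PRESETS[name]
    return spec if seed is None else replace(spec, seed=seed)
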