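"""Synthetic multi-omics data with planted, recoverable structure.

Two generators emulate the two inputs of the workflow:

* :func:`generate_compendium` — a genes x libraries expression background with
  a chosen number of libraries from the target tissue and a planted set of
  tissue-enriched genes whose target-tissue mean is elevated by a fixed number
  of background standard deviations.

* :func:`generate_cohort` — a joint genes+metabolites x samples matrix over a
  control/treatment cohort with (i) latent feature-profile groups that induce
  between-feature correlation, (ii) condition-discriminative features whose
  means shift between control and treatment, (iii) planted ratio "forks":
  metabolite triplets (A, B, C) with A linear in B/C at a condition-specific
  slope, and (iv) low-abundance-censored missingness on metabolites.

Every planted effect is recorded in :class:`PlantedTruth` so tests can score
recovery.  Outputs are deterministic functions of the spec and its seed; each
generator stage draws from its own named substream so regenerating one output
does not perturb the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .matrix_io import CONTROL, GENE, METABOLITE, TREATMENT, FeatureMatrix
from .enrichment import TissueCompendium

TARGET_TISSUE = "liver"
_BACKGROUND_TISSUES = ("brain", "muscle", "heart", "kidney", "spleen", "lung", "gonad")

# latent-scale constants: gene log-counts and metabolite log-abundances are
# affine images of the same unit-variance latent profile, so log + z-score
# recovers it exactly for both feature kinds
_GENE_LOG_MEAN, _GENE_LOG_SD_SPREAD, _GENE_LATENT_SCALE = 6.0, 0.5, 0.5
_MET_LOG_MEAN, _MET_LOG_SD_SPREAD, _MET_LATENT_SCALE = 2.0, 0.5, 0.7


@dataclass
class ForkSpec:
    """One planted triplet: A = intercept + slope_cond * (B/C) + noise."""

    slope_control: float
    slope_treatment: float
    noise_sd: float


@dataclass
class SyntheticSpec:
    """Parameters of the planted world.

    Counts mirror the study design this generator emulates: a ~16-library
    target-tissue slice of a multi-tissue compendium, and a cohort of 12
    control plus 11 treatment samples profiled on both omics layers.
    ``enrichment_effect``, ``profile_separation`` and ``discriminative_shift``
    are in units of the relevant noise standard deviation.
    """

    n_genes: int = 200
    n_metabolites: int = 100
    n_background_libraries: int = 50
    n_tissue_libraries: int = 16
    n_control_samples: int = 12
    n_treatment_samples: int = 11
    n_enriched_genes: int = 20
    enrichment_effect: float = 8.0
    n_profile_groups: int = 3
    profile_separation: float = 10.0
    n_discriminative: int = 10
    discriminative_shift: float = 3.0
    fork_specs: list[ForkSpec] = field(default_factory=list)
    missing_rate: float = 0.05
    rng_seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_genes",
            "n_metabolites",
            "n_background_libraries",
            "n_tissue_libraries",
            "n_control_samples",
            "n_treatment_samples",
            "n_enriched_genes",
            "n_profile_groups",
            "n_discriminative",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_enriched_genes > self.n_genes:
            raise ValueError("n_enriched_genes exceeds n_genes")
        if self.n_discriminative > self.n_genes + self.n_metabolites:
            raise ValueError("n_discriminative exceeds total feature count")
        if not 0 <= self.missing_rate < 1:
            raise ValueError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if 3 * len(self.fork_specs) > self.n_metabolites:
            raise ValueError(
                f"fork_specs need {3 * len(self.fork_specs)} metabolites "
                f"but n_metabolites={self.n_metabolites}"
            )
        if self.n_profile_groups < 1:
            raise ValueError("n_profile_groups must be >= 1")

    def substream(self, stage: str) -> np.random.Generator:
        """Independent, named RNG substream keyed on (seed, stage)."""
        ss = np.random.SeedSequence(self.rng_seed, spawn_key=(_STAGES[stage],))
        return np.random.default_rng(ss)


_STAGES = {"compendium": 0, "cohort": 1, "missing": 2}


@dataclass
class PlantedTruth:
    """Ground-truth record of everything the generator planted."""

    enriched_gene_ids: list[str] = field(default_factory=list)
    profile_group_of_feature: dict[str, int] = field(default_factory=dict)
    discriminative_ids: list[str] = field(default_factory=list)
    fork_triplets: list[tuple[str, str, str, float, float]] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["fork_triplets"] = [tuple(t) for t in d["fork_triplets"]]
        return cls(**d)


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:04d}" for i in range(1, n + 1)]


def _met_ids(n: int) -> list[str]:
    return [f"m{i:04d}" for i in range(1, n + 1)]


def generate_compendium(spec: SyntheticSpec) -> tuple[TissueCompendium, PlantedTruth]:
    """Simulate the multi-tissue enrichment background.

    Every gene has its own background mean and standard deviation; expression
    in every library is Gaussian around them.  For the planted enriched genes
    the target-tissue libraries are shifted up by
    ``enrichment_effect * sd(background)``; all other genes follow the
    background distribution in both library sets.
    """
    spec.validate()
    rng = spec.substream("compendium")

    genes = _gene_ids(spec.n_genes)
    tissue_libs = [f"{TARGET_TISSUE}_L{i:03d}" for i in range(1, spec.n_tissue_libraries + 1)]
    bg_libs = [f"bg_L{i:03d}" for i in range(1, spec.n_background_libraries + 1)]
    tissues = pd.Series(
        [TARGET_TISSUE] * len(tissue_libs)
        + [_BACKGROUND_TISSUES[i % len(_BACKGROUND_TISSUES)] for i in range(len(bg_libs))],
        index=tissue_libs + bg_libs,
    )

    mu = rng.normal(8.0, 2.0, size=spec.n_genes)
    sd = rng.uniform(0.5, 1.5, size=spec.n_genes)
    enriched = sorted(rng.choice(spec.n_genes, size=spec.n_enriched_genes, replace=False))
    shift = np.zeros(spec.n_genes)
    shift[enriched] = spec.enrichment_effect * sd[enriched]

    n_libs = len(tissue_libs) + len(bg_libs)
    vals = rng.normal(mu[:, None], sd[:, None], size=(spec.n_genes, n_libs))
    vals[:, : len(tissue_libs)] += shift[:, None]

    comp = TissueCompendium(pd.DataFrame(vals, index=genes, columns=tissue_libs + bg_libs), tissues)
    truth = PlantedTruth(enriched_gene_ids=[genes[i] for i in enriched])
    return comp, truth


def generate_cohort(spec: SyntheticSpec) -> tuple[FeatureMatrix, PlantedTruth]:
    """Simulate the joint gene+metabolite cohort matrix.

    Latent model: each non-fork feature i in profile group g has a
    unit-variance latent profile over samples

        x_i(s) = (sep * f_g(s) + eps_i(s)) / sqrt(1 + sep^2)
                 + shift * [i discriminative] * [s treated]

    where f_g is the group's shared per-sample factor, eps is idiosyncratic
    N(0, 1) noise, sep = ``profile_separation`` and shift =
    ``discriminative_shift`` (both in idiosyncratic-sd units; x itself has
    unit variance, so a within-group correlation of sep^2/(1+sep^2)).  Genes
    are emitted as rounded log-normal counts exp(mu_i + 0.5 x_i); metabolites
    as log-normal abundances exp(mu_i + 0.7 x_i) — both strictly positive and
    mapped back to x by log + z-score.

    Fork triplets are planted on dedicated metabolite ids (the last ones),
    outside the group structure: B and C are independent log-normals and
    A = 8 * noise_sd + slope_cond * (B/C) + N(0, noise_sd), floored at a tiny
    positive epsilon so abundances stay positive.

    Metabolite missingness is low-abundance censoring: entries in the bottom
    quartile of their compound go missing with probability
    min(1, 4 * missing_rate), an overall rate of about ``missing_rate``.
    """
    spec.validate()
    rng = spec.substream("cohort")

    genes = _gene_ids(spec.n_genes)
    mets = _met_ids(spec.n_metabolites)
    features = genes + mets
    ctrl = [f"ctrl_{i:02d}" for i in range(1, spec.n_control_samples + 1)]
    trt = [f"hs_{i:02d}" for i in range(1, spec.n_treatment_samples + 1)]
    samples = ctrl + trt
    n_s = len(samples)
    condition = pd.Series([CONTROL] * len(ctrl) + [TREATMENT] * len(trt), index=samples)
    treated = np.array([0.0] * len(ctrl) + [1.0] * len(trt))

    n_fork = len(spec.fork_specs)
    fork_members = mets[len(mets) - 3 * n_fork :] if n_fork else []
    grouped = [f for f in features if f not in set(fork_members)]

    # balanced random group assignment
    order = rng.permutation(len(grouped))
    group_of = {grouped[j]: int(i % spec.n_profile_groups) + 1 for i, j in enumerate(order)}

    disc = sorted(rng.choice(len(grouped), size=min(spec.n_discriminative, len(grouped)), replace=False))
    disc_ids = {grouped[i] for i in disc}

    sep = spec.profile_separation
    scale = np.sqrt(1.0 + sep**2)
    factors = rng.normal(size=(spec.n_profile_groups, n_s))

    vals = np.empty((len(features), n_s))
    fidx = {f: i for i, f in enumerate(features)}
    for f in grouped:
        x = (sep * factors[group_of[f] - 1] + rng.normal(size=n_s)) / scale
        if f in disc_ids:
            x = x + spec.discriminative_shift * treated
        if f.startswith("g"):
            lmu = rng.normal(_GENE_LOG_MEAN, _GENE_LOG_SD_SPREAD)
            vals[fidx[f]] = np.rint(np.exp(lmu + _GENE_LATENT_SCALE * x))
        else:
            lmu = rng.normal(_MET_LOG_MEAN, _MET_LOG_SD_SPREAD)
            vals[fidx[f]] = np.exp(lmu + _MET_LATENT_SCALE * x)

    truth = PlantedTruth(
        profile_group_of_feature=dict(sorted(group_of.items())),
        discriminative_ids=sorted(disc_ids),
    )

    for k, fs in enumerate(spec.fork_specs):
        a_id, b_id, c_id = fork_members[3 * k : 3 * k + 3]
        b = np.exp(rng.normal(1.0, 0.3, size=n_s))
        c = np.exp(rng.normal(1.0, 0.3, size=n_s))
        slope = np.where(treated > 0, fs.slope_treatment, fs.slope_control)
        noise = rng.normal(0.0, 1.0, size=n_s) * fs.noise_sd
        a = 8.0 * fs.noise_sd + slope * (b / c) + noise
        vals[fidx[a_id]] = np.maximum(a, 1e-9)
        vals[fidx[b_id]] = b
        vals[fidx[c_id]] = c
        truth.fork_triplets.append((a_id, b_id, c_id, fs.slope_control, fs.slope_treatment))

    df = pd.DataFrame(vals, index=features, columns=samples)

    if spec.missing_rate > 0 and spec.n_metabolites > 0:
        mrng = spec.substream("missing")
        p = min(1.0, 4.0 * spec.missing_rate)
        met_block = df.loc[mets]
        q25 = met_block.quantile(0.25, axis=1)
        censor = met_block.le(q25, axis=0) & (mrng.random(met_block.shape) < p)
        df.loc[mets] = met_block.mask(censor)

    kind = pd.Series([GENE] * len(genes) + [METABOLITE] * len(mets), index=features)
    return FeatureMatrix(df, kind, condition), truth
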