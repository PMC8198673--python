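"""Synthetic multiomics case/control cohorts.

The generator reproduces the statistical shape of stool-sample case/control
studies that pair 16S genus abundances with metabolite intensities under class
imbalance: zero-inflated compositional microbial counts (Dirichlet-multinomial
reads at a configurable sequencing depth), heavy-tailed positive metabolite
intensities (log-normal), and age/sex covariates.  The binary outcome is
generated through a probit link on standardised transformed features, with
configurable main effects and pairwise interaction effects, so selection and
interaction-mining stages can be tested against planted truth.

A separate negative-binomial count simulator provides gene-by-sample matrices
with planted fold changes for the bulk-transcriptomics workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import ndtr

MICROBIOME = "microbiome"
METABOLOME = "metabolome"
COVARIATE = "covariate"
LAYERS = (MICROBIOME, METABOLOME, COVARIATE)


@dataclass
class FeatureTable:
    """Labelled sample-by-feature matrix with per-feature omics-layer tags.

    ``values`` holds raw feature values (microbial counts >= 0, metabolite
    intensities > 0, covariates as-is); ``outcome`` is 1 for cases.
    """

    sample_ids: list
    feature_ids: list
    layers: np.ndarray  # per-feature tag, one of LAYERS
    values: np.ndarray  # (n_samples, n_features)
    outcome: np.ndarray  # (n_samples,) in {0, 1}

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.outcome = np.asarray(self.outcome, dtype=int)
        self.layers = np.asarray(self.layers, dtype=object)
        n, p = self.values.shape
        if len(self.sample_ids) != n or len(self.feature_ids) != p:
            raise ValueError("inconsistent dimensions")
        if len(self.layers) != p:
            raise ValueError("one layer tag per feature required")
        if len(set(self.feature_ids)) != p:
            raise ValueError("feature ids must be unique")
        if np.isnan(self.values).any():
            raise ValueError("missing values are not allowed")
        if not set(np.unique(self.outcome)) <= {0, 1}:
            raise ValueError("outcome must be binary 0/1")
        bad = set(self.layers) - set(LAYERS)
        if bad:
            raise ValueError(f"unknown layer tags: {sorted(bad)}")
        mic = self.layers == MICROBIOME
        if mic.any() and (self.values[:, mic] < 0).any():
            raise ValueError("microbiome values must be non-negative")
        met = self.layers == METABOLOME
        if met.any() and (self.values[:, met] <= 0).any():
            raise ValueError("metabolome values must be positive")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"unknown feature: {feature_id!r}") from None

    def layer_of(self, feature_id: str) -> str:
        return str(self.layers[self.column(feature_id)])

    # -- subsetting ---------------------------------------------------------

    def take(self, sample_indices) -> "FeatureTable":
        idx = np.asarray(sample_indices, dtype=int)
        return FeatureTable(
            sample_ids=[self.sample_ids[i] for i in idx],
            feature_ids=list(self.feature_ids),
            layers=self.layers.copy(),
            values=self.values[idx],
            outcome=self.outcome[idx],
        )

    def restrict(self, feature_ids: Sequence[str]) -> "FeatureTable":
        cols = [self.column(f) for f in feature_ids]
        return FeatureTable(
            sample_ids=list(self.sample_ids),
            feature_ids=list(feature_ids),
            layers=self.layers[cols],
            values=self.values[:, cols],
            outcome=self.outcome.copy(),
        )

    def select_layers(self, layers: Sequence[str],
                      keep_covariates: bool = True) -> "FeatureTable":
        wanted = set(layers)
        if keep_covariates:
            wanted.add(COVARIATE)
        keep = [f for f, l in zip(self.feature_ids, self.layers) if l in wanted]
        return self.restrict(keep)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.sample_ids,
                          columns=self.feature_ids)
        df["outcome"] = self.outcome
        return df


@dataclass
class CohortSpec:
    """Study-design parameters for one synthetic cohort.

    Defaults mirror a stool-sample colorectal-cancer case/control study with
    over-represented controls: 102 controls vs 36 cases, genus-level counts at
    a mean depth of 10,000 reads with ~30% excess zeros, and log-normal
    metabolite intensities.  Effects are on the probit scale and act on
    z-scored transformed features (log(x+1) counts, log intensities), so
    coefficients are comparable across omics layers.
    """

    n_controls: int = 102
    n_cases: int = 36
    n_taxa: int = 30
    n_metabolites: int = 40
    include_covariates: bool = True
    main_effects: Tuple[Tuple[str, float], ...] = ()
    interaction_effects: Tuple[Tuple[str, str, float], ...] = ()
    zero_inflation: float = 0.3
    sequencing_depth: float = 10_000.0
    dispersion: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_controls < 1 or self.n_cases < 1:
            raise ValueError("both class sizes must be positive")
        if self.n_controls + self.n_cases < 2:
            raise ValueError("need at least two samples")
        if self.n_taxa < 1 or self.n_metabolites < 1:
            raise ValueError("feature counts must be positive")
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ValueError("zero_inflation must lie in [0, 1]")
        if self.sequencing_depth <= 0:
            raise ValueError("sequencing_depth must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    @property
    def n_samples(self) -> int:
        return self.n_controls + self.n_cases


def transformed_standardized(table: FeatureTable) -> np.ndarray:
    """Z-scored transformed design: log(x+1) for microbial counts, log(x) for
    metabolite intensities, covariates untouched before z-scoring.  Constant
    columns standardise to zero."""
    Z = table.values.copy()
    mic = table.layers == MICROBIOME
    met = table.layers == METABOLOME
    Z[:, mic] = np.log1p(Z[:, mic])
    Z[:, met] = np.log(Z[:, met])
    mu = Z.mean(axis=0)
    sd = Z.std(axis=0)
    sd[sd == 0] = 1.0
    return (Z - mu) / sd


def _calibrate_intercept(eta: np.ndarray, n_cases: int) -> float:
    """Bisection for the probit intercept making the expected case count match."""
    lo, hi = -20.0, 20.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if ndtr(mid + eta).sum() < n_cases:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(spec: CohortSpec) -> FeatureTable:
    """Generate one linked microbiome-metabolome cohort (deterministic per seed).

    Labels are drawn from the probit model conditional on the exact requested
    class counts: the intercept is calibrated so the expected case count equals
    ``n_cases``, then Bernoulli label vectors are rejected until the class
    split is exact (budget 1000 attempts).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples

    # microbial counts: zero-inflated Dirichlet-multinomial
    base_w = rng.lognormal(mean=0.0, sigma=1.5, size=spec.n_taxa)
    base_p = base_w / base_w.sum()
    conc = base_p / spec.dispersion
    depth = rng.poisson(spec.sequencing_depth, size=n)
    gams = rng.gamma(shape=conc, scale=1.0, size=(n, spec.n_taxa))
    if spec.zero_inflation > 0:
        drop = rng.random((n, spec.n_taxa)) < spec.zero_inflation
        gams[drop] = 0.0
    dead = gams.sum(axis=1) == 0
    if dead.any():  # pathological zero-inflation: keep the dominant taxon
        gams[dead, int(np.argmax(conc))] = 1.0
    props = gams / gams.sum(axis=1, keepdims=True)
    counts = np.empty((n, spec.n_taxa), dtype=float)
    for i in range(n):
        counts[i] = rng.multinomial(depth[i], props[i])

    # metabolite intensities: per-metabolite log-normal
    met_mu = rng.normal(10.0, 1.0, size=spec.n_metabolites)
    met_sd = rng.uniform(0.3, 1.0, size=spec.n_metabolites)
    intensities = np.exp(rng.normal(met_mu, met_sd,
                                    size=(n, spec.n_metabolites)))

    blocks = [counts, intensities]
    feature_ids = [f"OTU{i + 1}" for i in range(spec.n_taxa)]
    feature_ids += [f"M{i + 1}" for i in range(spec.n_metabolites)]
    layers = [MICROBIOME] * spec.n_taxa + [METABOLOME] * spec.n_metabolites
    if spec.include_covariates:
        age = rng.uniform(30.0, 80.0, size=n)
        sex = rng.integers(0, 2, size=n).astype(float)
        blocks.append(np.column_stack([age, sex]))
        feature_ids += ["age", "sex"]
        layers += [COVARIATE, COVARIATE]

    values = np.column_stack(blocks)
    table = FeatureTable(
        sample_ids=[f"S{i + 1:04d}" for i in range(n)],
        feature_ids=feature_ids,
        layers=np.asarray(layers, dtype=object),
        values=values,
        outcome=np.zeros(n, dtype=int),
    )

    # probit score on standardised transformed features
    Z = transformed_standardized(table)
    col = {f: i for i, f in enumerate(feature_ids)}
    eta = np.zeros(n)
    for fid, beta in spec.main_effects:
        if fid not in col:
            raise KeyError(f"main effect references unknown feature {fid!r}")
        eta += beta * Z[:, col[fid]]
    for fa, fb, gamma in spec.interaction_effects:
        for fid in (fa, fb):
            if fid not in col:
                raise KeyError(
                    f"interaction effect references unknown feature {fid!r}")
        eta += gamma * Z[:, col[fa]] * Z[:, col[fb]]

    intercept = _calibrate_intercept(eta, spec.n_cases)
    prob = ndtr(intercept + eta)

    outcome = None
    for _ in range(1000):
        y = (rng.random(n) < prob).astype(int)
        if y.sum() == spec.n_cases:
            outcome = y
            break
    if outcome is None:
        raise RuntimeError(
            "could not realise the requested class split within 1000 draws; "
            f"effect sizes too extreme (main={spec.main_effects}, "
            f"interaction={spec.interaction_effects})")
    table.outcome = outcome
    return table


def simulate_counts(n_genes: int, n_normal: int, n_tumour: int,
                    fold_changes: Optional[dict] = None,
                    dispersion: float = 0.1,
                    seed: int = 0):
    """Negative-binomial gene-by-sample counts with planted fold changes.

    Per-gene baseline means are log-uniform over roughly 3-1000; tumour-group
    means are multiplied by the gene's fold change.  The NB variance follows
    mu + dispersion * mu^2.  Returns (DataFrame genes x samples, labels) with
    labels 0 = normal, 1 = tumour, deterministic for a given seed.
    """
    if n_genes < 1 or n_normal < 1 or n_tumour < 1:
        raise ValueError("all counts must be positive")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    fold_changes = dict(fold_changes or {})
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    for g, fc in fold_changes.items():
        if g not in genes:
            raise KeyError(f"fold change references unknown gene {g!r}")
        if fc <= 0:
            raise ValueError(f"fold change for {g} must be positive")

    rng = np.random.default_rng(seed)
    base = 10.0 ** rng.uniform(0.5, 3.0, size=n_genes)
    fc = np.ones(n_genes)
    gindex = {g: i for i, g in enumerate(genes)}
    for g, ratio in fold_changes.items():
        fc[gindex[g]] = ratio

    n = n_normal + n_tumour
    mu = np.tile(base[:, None], (1, n))
    mu[:, n_normal:] *= fc[:, None]
    r = 1.0 / dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    samples = [f"N{i + 1}" for i in range(n_normal)]
    samples += [f"T{i + 1}" for i in range(n_tumour)]
    labels = np.array([0] * n_normal + [1] * n_tumour)
    return pd.DataFrame(counts, index=genes, columns=samples), labels
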