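"""Seeded generator for factorial soil ionome / enzyme-activity datasets.

The generator emulates the sampling design of a multi-site long-term
fertilization trial: ``n_sites`` experimental sites × 2 fertilization
treatments (CF = chemical fertilizer only, COF = chemical + organic
fertilizer) × ``n_replicates`` field replicates, with 19 exchangeable-ion
and 7 enzyme-activity variables by default (24 samples in total under the
default design).

Data model (all planted structure is exposed through :class:`EffectTruth`):

* every variable has a lognormal baseline level;
* sites act as per-variable multiplicative offsets (log-scale SD
  ``site_effect_sd``) — this is what makes "site" a major variance
  component downstream;
* the COF cell mean of variable *v* equals the CF cell mean times
  ``exp(treatment_log_ratio[v])`` — effects are planted on *cell means*,
  not on lognormal μ, so the log response ratio of means recovers the
  planted value without the lognormal mean bias ``exp(μ + σ²/2)``;
* within-cell noise is lognormal with coefficient of variation
  ``noise_cv`` (positive, right-skewed measurements);
* variables in a *correlation block* share a latent factor, in both their
  site offsets and their within-cell noise, with per-variable loadings in
  [−1, 1]; the induced log-scale correlation between two block members is
  the product of their loadings, so high-|loading| blocks plant network
  edges of the loading-sign product;
* soil pH is a covariate: CF cells sit ``ph_cf_depression`` units below
  the COF cells of the same site (chemical-only fertilization acidifies).

Draw order from one seed is fixed (baselines → site offsets → pH → noise,
each from its own spawned substream), so identical seeds give bit-identical
datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .io_model import Metadata, SampleTable, ValidationError

ION_NAMES = (
    "B", "Na", "Al", "P", "K", "Ti", "Cr", "Mn", "Fe", "Co",
    "Ni", "Cu", "Zn", "As", "Mo", "Cd", "La", "Pb", "Ca",
)
ENZYME_NAMES = (
    "acid_phosphomonoesterase",
    "sulfatase",
    "beta_glucosidase",
    "beta_cellobiosidase",
    "N_acetyl_glucosaminidase",
    "beta_xylosidase",
    "alpha_glucosidase",
)
SITE_NAMES = ("JL", "SD", "AH", "HN")

# Default planted treatment effects (log COF/CF ratio of cell means).
# Signs follow the directions reported for long-term organic amendment:
# acid-mobilised metals (Al, Fe, Pb, La, Ni, Co) higher under CF (negative
# ratio), manure-borne nutrients (P, Zn, Cu, Cd, Mo) higher under COF, and
# most enzyme activities stimulated by organic input with α-glucosidase
# the strongest responder.  Al (−1.2) and P (+1.0) are the extremes.
DEFAULT_LOG_RATIOS: Mapping[str, float] = {
    "Al": -1.2, "Fe": -0.45, "Pb": -0.5, "La": -0.45, "Ni": -0.4, "Co": -0.4,
    "P": 1.0, "Zn": 0.35, "Cu": 0.3, "Cd": 0.45, "Mo": 0.4,
    "alpha_glucosidase": 0.8,
    "beta_xylosidase": 0.45,
    "sulfatase": 0.4,
    "beta_cellobiosidase": 0.35,
    "beta_glucosidase": 0.2,
    "acid_phosphomonoesterase": 0.2,
    "N_acetyl_glucosaminidase": 0.15,
}


@dataclass(frozen=True)
class CorrelationBlock:
    """A group of variables sharing one latent factor.

    ``loadings`` maps variable_id → loading in [−1, 1]; the planted
    log-scale correlation between members u, v is loading_u · loading_v.
    """

    name: str
    loadings: Mapping[str, float]

    def __post_init__(self):
        object.__setattr__(self, "loadings", dict(self.loadings))
        for var, lam in self.loadings.items():
            if not -1.0 <= lam <= 1.0:
                raise ValidationError(
                    f"loading {lam} for {var!r} in block {self.name!r} outside [-1, 1]"
                )


def _default_blocks() -> tuple:
    return (
        CorrelationBlock(
            "acid_metals",
            {
                "Al": 0.92, "Fe": 0.92, "Pb": 0.9, "La": 0.9, "Co": 0.9, "Ni": 0.9,
                # glucosidases anti-correlate with the acid-metal axis,
                # giving the planted networks their negative enzyme–ion edges
                "alpha_glucosidase": -0.9,
                "beta_glucosidase": -0.85,
            },
        ),
        CorrelationBlock(
            "manure_inputs",
            {
                "P": 0.9, "Zn": 0.9, "Cu": 0.88, "Cd": 0.88, "Mo": 0.85,
                "beta_xylosidase": 0.85,
                "sulfatase": 0.8,
            },
        ),
    )


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic study; defaults are the emulated design."""

    n_sites: int = 4
    n_treatments: int = 2
    n_replicates: int = 3
    n_ions: int = 19
    n_enzymes: int = 7
    site_effect_sd: float = 0.4
    treatment_log_ratio: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOG_RATIOS)
    )
    noise_cv: float = 0.2
    ph_base: float = 6.8
    ph_cf_depression: float = 1.1
    ph_site_sd: float = 0.3
    ph_noise_sd: float = 0.1
    correlation_blocks: tuple = field(default_factory=_default_blocks)
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "treatment_log_ratio", dict(self.treatment_log_ratio))
        object.__setattr__(self, "correlation_blocks", tuple(self.correlation_blocks))
        for name, value in (
            ("n_sites", self.n_sites), ("n_replicates", self.n_replicates),
            ("n_ions", self.n_ions), ("n_enzymes", self.n_enzymes),
        ):
            if value < 1:
                raise ValidationError(f"{name} must be positive, got {value}")
        if self.n_treatments != 2:
            raise ValidationError("the design is fixed at 2 treatments (CF, COF)")
        if self.noise_cv <= 0:
            raise ValidationError("noise_cv must be > 0")
        if self.site_effect_sd < 0:
            raise ValidationError("site_effect_sd must be >= 0")
        names = set(self.variable_ids)
        seen: dict = {}
        for block in self.correlation_blocks:
            for var in block.loadings:
                if var not in names:
                    raise ValidationError(
                        f"block {block.name!r} references unknown variable {var!r}"
                    )
                if var in seen:
                    raise ValidationError(
                        f"variable {var!r} appears in blocks {seen[var]!r} and {block.name!r}; "
                        "a variable may belong to at most one block"
                    )
                seen[var] = block.name
        unknown_ratio = set(self.treatment_log_ratio) - names
        if unknown_ratio:
            raise ValidationError(
                f"treatment_log_ratio references unknown variables {sorted(unknown_ratio)}"
            )

    @property
    def ion_ids(self) -> tuple:
        base = list(ION_NAMES[: self.n_ions])
        base += [f"ion{k}" for k in range(len(base) + 1, self.n_ions + 1)]
        return tuple(base)

    @property
    def enzyme_ids(self) -> tuple:
        base = list(ENZYME_NAMES[: self.n_enzymes])
        base += [f"enzyme{k}" for k in range(len(base) + 1, self.n_enzymes + 1)]
        return tuple(base)

    @property
    def variable_ids(self) -> tuple:
        return self.ion_ids + self.enzyme_ids

    @property
    def site_ids(self) -> tuple:
        base = list(SITE_NAMES[: self.n_sites])
        base += [f"S{k}" for k in range(len(base) + 1, self.n_sites + 1)]
        return tuple(base)


def default_config(**overrides) -> SynthConfig:
    """The emulated study design: 4 sites × 2 treatments × 3 replicates,
    19 ions + 7 enzymes, planted ratios spanning −1.2 (Al) to +1.0 (P)."""
    return replace(SynthConfig(), **overrides) if overrides else SynthConfig()


@dataclass(frozen=True)
class EffectTruth:
    """Planted ground truth exposed for parameter-recovery tests."""

    log_ratios: Mapping[str, float]          # variable → planted log COF/CF ratio
    categories: Mapping[str, str]            # variable → ion|enzyme
    block_of: Mapping[str, tuple]            # variable → (block name, loading); absent if unblocked
    ph_difference: float                     # mean pH(COF) − pH(CF)

    def __post_init__(self):
        object.__setattr__(self, "log_ratios", dict(self.log_ratios))
        object.__setattr__(self, "categories", dict(self.categories))
        object.__setattr__(self, "block_of", dict(self.block_of))


def generate_dataset(config: SynthConfig):
    """Generate (ion_table, enzyme_table, metadata, truth) for one seed.

    Cell means satisfy mean(site, COF) = mean(site, CF) · exp(δ_v) exactly
    before noise; within-cell values are lognormal with CV ``noise_cv``.
    """
    if config.n_replicates < 2:
        raise ValidationError(
            "n_replicates must be >= 2: downstream variance estimation is undefined"
        )

    ss = np.random.SeedSequence(config.seed)
    base_rng, site_rng, ph_rng, noise_rng = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    ions, enzymes = config.ion_ids, config.enzyme_ids
    variables = list(ions) + list(enzymes)
    categories = {v: ("ion" if v in set(ions) else "enzyme") for v in variables}
    n_vars = len(variables)
    sites = config.site_ids
    n_sites = config.n_sites

    block_of: dict = {}
    for block in config.correlation_blocks:
        for var, lam in block.loadings.items():
            block_of[var] = (block.name, float(lam))

    delta = np.array(
        [config.treatment_log_ratio.get(v, 0.0) for v in variables], dtype=float
    )

    # --- baseline levels (variable order: ions then enzymes) ---------------
    baselines = np.empty(n_vars)
    for j, var in enumerate(variables):
        centre = np.log(50.0) if categories[var] == "ion" else np.log(120.0)
        spread = 1.0 if categories[var] == "ion" else 0.8
        baselines[j] = np.exp(base_rng.normal(centre, spread))

    # --- site offsets (standard normals scaled by site_effect_sd) ---------
    eta = site_rng.standard_normal((n_sites, n_vars))          # idiosyncratic
    block_site = {
        block.name: site_rng.standard_normal(n_sites)
        for block in config.correlation_blocks
    }
    site_log_offset = np.empty((n_sites, n_vars))
    for j, var in enumerate(variables):
        if var in block_of:
            name, lam = block_of[var]
            shared = block_site[name]
            mix = lam * shared + np.sqrt(1.0 - lam ** 2) * eta[:, j]
        else:
            mix = eta[:, j]
        site_log_offset[:, j] = config.site_effect_sd * mix

    # --- sample frame ------------------------------------------------------
    rows = []
    for s_idx, site in enumerate(sites):
        for treatment in ("CF", "COF"):
            for rep in range(1, config.n_replicates + 1):
                rows.append((f"{site}_{treatment}_{rep}", site, s_idx, treatment, rep))
    n_samples = len(rows)

    # --- pH covariate ------------------------------------------------------
    site_ph_shift = config.ph_site_sd * ph_rng.standard_normal(n_sites)
    ph_noise = config.ph_noise_sd * ph_rng.standard_normal(n_samples)
    ph = np.empty(n_samples)
    for i, (_, _, s_idx, treatment, _) in enumerate(rows):
        ph[i] = config.ph_base + site_ph_shift[s_idx] + ph_noise[i]
        if treatment == "CF":
            ph[i] -= config.ph_cf_depression
    ph = np.clip(ph, 0.0, 14.0)

    # --- within-cell lognormal noise with block-shared latents -------------
    sigma = np.sqrt(np.log1p(config.noise_cv ** 2))
    eps = noise_rng.standard_normal((n_samples, n_vars))       # idiosyncratic
    latent = {
        block.name: noise_rng.standard_normal(n_samples)
        for block in config.correlation_blocks
    }
    e = np.empty((n_samples, n_vars))
    for j, var in enumerate(variables):
        if var in block_of:
            name, lam = block_of[var]
            e[:, j] = lam * latent[name] + np.sqrt(1.0 - lam ** 2) * eps[:, j]
        else:
            e[:, j] = eps[:, j]

    values = np.empty((n_samples, n_vars))
    for i, (_, _, s_idx, treatment, _) in enumerate(rows):
        cell_mean = baselines * np.exp(site_log_offset[s_idx])
        if treatment == "COF":
            cell_mean = cell_mean * np.exp(delta)
        # E[exp(σe − σ²/2)] = 1, so the cell mean is hit exactly in expectation
        values[i] = cell_mean * np.exp(sigma * e[i] - 0.5 * sigma ** 2)

    sample_ids = tuple(r[0] for r in rows)
    ion_table = SampleTable(sample_ids, ions, ("ion",) * len(ions),
                            values[:, : len(ions)])
    enzyme_table = SampleTable(sample_ids, enzymes, ("enzyme",) * len(enzymes),
                               values[:, len(ions):])
    metadata = Metadata(pd.DataFrame({
        "sample_id": sample_ids,
        "site": [r[1] for r in rows],
        "fertilization": [r[3] for r in rows],
        "replicate": [r[4] for r in rows],
        "pH": ph,
    }))
    truth = EffectTruth(
        log_ratios={v: float(d) for v, d in zip(variables, delta)},
        categories=categories,
        block_of=block_of,
        ph_difference=float(config.ph_cf_depression),
    )
    return ion_table, enzyme_table, metadata, truth


def truth_report(truth: EffectTruth) -> pd.DataFrame:
    """One row per generated variable: planted ratio and block membership."""
    records = []
    for var, ratio in truth.log_ratios.items():
        block, loading = truth.block_of.get(var, ("", float("nan")))
        records.append({
            "variable_id": var,
            "category": truth.categories[var],
            "true_log_ratio": ratio,
            "block": block,
            "loading": loading,
        })
    return pd.DataFrame.from_records(records)


def config_from_yaml(path) -> SynthConfig:
    """Load a SynthConfig from a YAML key-value file.

    Recognised keys mirror the dataclass fields; ``correlation_blocks`` is
    a mapping of block name → {variable: loading}; ``treatment_log_ratio``
    a mapping of variable → log ratio.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError("synthetic config file must hold a key-value mapping")
    if "correlation_blocks" in raw:
        blocks = raw.pop("correlation_blocks")
        raw["correlation_blocks"] = tuple(
            CorrelationBlock(name, loadings) for name, loadings in blocks.items()
        )
    unknown = set(raw) - set(SynthConfig.__dataclass_fields__)
    if unknown:
        raise ValidationError(f"unknown synthetic config keys: {sorted(unknown)}")
    return SynthConfig(**raw)
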