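"""Synthetic trial-data generator.

No raw data accompany the study this package analyses, so every stage is
exercised on generated datasets that carry the same statistical structure
the analysis assumes: a randomized complete block design with five
nitrogen-substitution treatments (CK, 25%, 50%, 75%, 100% manure N),
three replicates, and two sampled depth layers (0-20 and 20-40 cm).

Per-variable values are drawn independently from Normal(mean_t, SD_t),
where mean_t is the CK mean times a treatment x depth multiplicative
effect, and SD_t = CV x mean_t.  Yield and root traits use explicit
per-treatment means and SDs (the trial's printed summary values) at plot
level.  Negative draws are truncated at zero.  Bacterial communities are
drawn per sample as Dirichlet phylum proportions times a multinomial read
count, mirroring amplicon count structure without modelling reads.

Default effect multipliers house the reported treatment responses:
topsoil gains in SOC, TN, microbial biomass, available P, water content
and all six hydrolases with a drop in dissolved organic N; subsoil gains
confined to microbial biomass, water and the N/P-acquiring peptidase and
phosphatase, against declines in mineral nutrients, bulk density and the
C-acquiring hydrolases.  Ranges are interpolated linearly across the four
substitution rates (monotone in rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .community import CommunityTable

__all__ = [
    "ConfigError",
    "GeneratorConfig",
    "TrialDataset",
    "default_config",
    "generate_trial",
    "generate_community",
]

TREATMENTS = ("CK", "25%", "50%", "75%", "100%")
DEPTHS = ("0-20", "20-40")
SUBSTITUTION = ("25%", "50%", "75%", "100%")


class ConfigError(ValueError):
    """Invalid generator configuration."""


def _ramp(lo: float, hi: float) -> dict[str, float]:
    """Linear interpolation of an effect multiplier across the four
    substitution rates (CK is always 1)."""
    values = np.linspace(lo, hi, num=len(SUBSTITUTION))
    out = {"CK": 1.0}
    out.update({t: float(v) for t, v in zip(SUBSTITUTION, values)})
    return out


def _flat() -> dict[str, float]:
    return {t: 1.0 for t in TREATMENTS}


@dataclass
class IndicatorSpec:
    """Gaussian spec for one soil variable: CK mean per depth, CV, and a
    per-treatment multiplicative effect per depth."""

    ck_mean: dict[str, float]
    cv: float
    effects: dict[str, dict[str, float]]  # depth -> treatment -> multiplier
    unit: str = ""


def _default_indicator_specs() -> dict[str, IndicatorSpec]:
    # CK topsoil baselines follow the site description (SOC 21.9 g kg-1,
    # AHN 99.8 mg kg-1, BD 1.58 g cm-3); the rest are typical Mollisol
    # cropland values.  Effects interpolate the reported percent-change
    # ranges between the 25% and 100% substitution rates.
    top, sub = DEPTHS
    spec = {
        "SOC": IndicatorSpec({top: 21.9, sub: 15.0}, 0.08,
                             {top: _ramp(1.06, 1.10), sub: _flat()}, "g kg-1"),
        "TN": IndicatorSpec({top: 1.60, sub: 1.10}, 0.08,
                            {top: _ramp(1.04, 1.08), sub: _ramp(0.98, 0.83)}, "g kg-1"),
        "MBC": IndicatorSpec({top: 280.0, sub: 150.0}, 0.08,
                             {top: _ramp(1.28, 1.42), sub: _ramp(1.92, 2.12)}, "mg kg-1"),
        "MBN": IndicatorSpec({top: 40.0, sub: 20.0}, 0.08,
                             {top: _ramp(1.32, 2.12), sub: _ramp(1.28, 1.59)}, "mg kg-1"),
        "DOC": IndicatorSpec({top: 180.0, sub: 120.0}, 0.08,
                             {top: _flat(), sub: _flat()}, "mg kg-1"),
        "DON": IndicatorSpec({top: 25.0, sub: 15.0}, 0.08,
                             {top: _ramp(0.77, 0.69), sub: _ramp(0.55, 0.48)}, "mg kg-1"),
        "AHN": IndicatorSpec({top: 99.8, sub: 70.0}, 0.08,
                             {top: _flat(), sub: _flat()}, "mg kg-1"),
        "AP": IndicatorSpec({top: 20.0, sub: 12.0}, 0.08,
                            {top: _ramp(1.22, 1.59), sub: _ramp(0.58, 0.40)}, "mg kg-1"),
        "AK": IndicatorSpec({top: 150.0, sub: 110.0}, 0.08,
                            {top: _flat(), sub: _ramp(0.83, 0.65)}, "mg kg-1"),
        "BD": IndicatorSpec({top: 1.58, sub: 1.62}, 0.03,
                            {top: _flat(), sub: _ramp(0.92, 0.86)}, "g cm-3"),
        "SW": IndicatorSpec({top: 22.0, sub: 20.0}, 0.06,
                            {top: _ramp(1.05, 1.22), sub: _ramp(1.06, 1.22)}, "%"),
    }
    return spec


def _default_enzyme_specs() -> dict[str, IndicatorSpec]:
    top, sub = DEPTHS
    return {
        "BG": IndicatorSpec({top: 120.0, sub: 60.0}, 0.10,
                            {top: _ramp(1.15, 1.67), sub: _ramp(0.54, 0.32)}, "nmol g-1 h-1"),
        "CB": IndicatorSpec({top: 25.0, sub: 15.0}, 0.10,
                            {top: _ramp(2.38, 3.39), sub: _ramp(0.88, 0.60)}, "nmol g-1 h-1"),
        "XYL": IndicatorSpec({top: 30.0, sub: 18.0}, 0.10,
                             {top: _ramp(1.58, 2.17), sub: _ramp(0.72, 0.41)}, "nmol g-1 h-1"),
        "NAG": IndicatorSpec({top: 45.0, sub: 25.0}, 0.10,
                             {top: _ramp(1.52, 1.74), sub: _ramp(0.60, 0.47)}, "nmol g-1 h-1"),
        "LAP": IndicatorSpec({top: 35.0, sub: 20.0}, 0.10,
                             {top: _ramp(2.12, 2.85), sub: _ramp(1.67, 2.55)}, "nmol g-1 h-1"),
        "ALP": IndicatorSpec({top: 150.0, sub: 80.0}, 0.10,
                             {top: _ramp(1.78, 2.25), sub: _ramp(1.27, 2.18)}, "nmol g-1 h-1"),
    }


def _default_yield_root_specs() -> dict[str, dict[str, tuple[float, float]]]:
    # Printed per-treatment means +- SD for yield and root traits.
    return {
        "yield": dict(zip(TREATMENTS, [(11.3, 0.83), (11.7, 1.46), (10.3, 0.69),
                                       (8.35, 1.22), (4.03, 0.35)])),
        "root_biomass": dict(zip(TREATMENTS, [(19.2, 2.02), (18.4, 0.97), (15.5, 1.03),
                                              (16.4, 1.41), (13.5, 1.39)])),
        "root_length": dict(zip(TREATMENTS, [(5.86, 0.86), (5.12, 0.66), (4.99, 0.43),
                                             (4.92, 0.42), (3.32, 0.34)])),
        "root_surface_area": dict(zip(TREATMENTS, [(13.9, 2.44), (12.6, 1.69), (10.2, 1.44),
                                                   (11.9, 1.93), (7.09, 1.23)])),
        "root_volume": dict(zip(TREATMENTS, [(26.2, 5.63), (24.9, 3.75), (15.6, 1.88),
                                             (21.5, 3.28), (12.2, 3.38)])),
    }

YIELD_ROOT_UNITS = {
    "yield": "Mg ha-1",
    "root_biomass": "g plant-1",
    "root_length": "1e3 cm plant-1",
    "root_surface_area": "1e2 cm2 plant-1",
    "root_volume": "cm3 plant-1",
}


@dataclass
class CommunitySpec:
    """Phylum-level Dirichlet composition per treatment x depth."""

    baseline: dict[str, dict[str, float]]  # depth -> phylum -> CK mean
    fold_changes: dict[str, dict[str, dict[str, float]]]  # depth -> phylum -> treatment -> fold
    concentration: float = 500.0
    reads_per_sample: int = 10_000
    taxa_per_phylum: int = 3

    def mean_vector(self, treatment: str, depth: str) -> pd.Series:
        base = pd.Series(self.baseline[depth], dtype=float)
        folds = pd.Series(
            {ph: self.fold_changes.get(depth, {}).get(ph, {}).get(treatment, 1.0)
             for ph in base.index}
        )
        vec = base * folds
        return vec / vec.sum()


def _default_community_spec() -> CommunitySpec:
    top, sub = DEPTHS
    baseline = {
        top: {
            "Pseudomonadota": 0.26, "Actinomycetota": 0.20,
            "Acidobacteriota": 0.16, "Chloroflexota": 0.10,
            "Bacteroidota": 0.06, "Gemmatimonadota": 0.05,
            "Bacillota": 0.04, "Planctomycetota": 0.05,
            "Verrucomicrobiota": 0.03, "Methylomirabilota": 0.02,
            "Other": 0.03,
        },
        sub: {
            "Pseudomonadota": 0.22, "Actinomycetota": 0.24,
            "Acidobacteriota": 0.17, "Chloroflexota": 0.11,
            "Bacteroidota": 0.04, "Gemmatimonadota": 0.04,
            "Bacillota": 0.05, "Planctomycetota": 0.04,
            "Verrucomicrobiota": 0.03, "Methylomirabilota": 0.03,
            "Other": 0.03,
        },
    }
    fold_changes = {
        top: {
            "Actinomycetota": _ramp(1.14, 1.28),
            "Acidobacteriota": _ramp(1.12, 1.35),
            "Gemmatimonadota": _ramp(1.64, 1.88),
            "Methylomirabilota": _ramp(1.55, 2.01),
            "Bacteroidota": _ramp(0.79, 0.43),
            "Chloroflexota": _ramp(0.85, 0.76),
            "Pseudomonadota": _ramp(0.87, 0.71),
        },
        sub: {
            "Pseudomonadota": _ramp(1.05, 1.06),
            "Acidobacteriota": _ramp(1.11, 1.18),
            "Bacillota": _ramp(1.12, 1.21),
            "Actinomycetota": _ramp(0.88, 0.80),
        },
    }
    return CommunitySpec(baseline=baseline, fold_changes=fold_changes)


@dataclass
class GeneratorConfig:
    """Full specification of one synthetic trial."""

    treatments: tuple[str, ...] = TREATMENTS
    replicates: int = 3
    depths: tuple[str, ...] = DEPTHS
    indicator_specs: dict[str, IndicatorSpec] = field(
        default_factory=_default_indicator_specs)
    enzyme_specs: dict[str, IndicatorSpec] = field(
        default_factory=_default_enzyme_specs)
    yield_root_specs: dict = field(default_factory=_default_yield_root_specs)
    community_spec: CommunitySpec | None = field(
        default_factory=_default_community_spec)
    seed: int = 42
    block_sd: float = 0.0  # optional additive replicate (block) effect, in CV units
    indicator_correlation: float = 0.0  # shared-latent correlation across indicators

    def validate(self) -> None:
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if not 0.0 <= self.indicator_correlation < 1.0:
            raise ConfigError("indicator_correlation must be in [0, 1)")
        for name, spec in {**self.indicator_specs, **self.enzyme_specs}.items():
            if spec.cv < 0:
                raise ConfigError(f"indicator {name!r}: CV must be >= 0")
            for depth in self.depths:
                if depth not in spec.ck_mean:
                    raise ConfigError(f"indicator {name!r}: no CK mean for depth {depth!r}")
                effects = spec.effects.get(depth, {})
                for t in effects:
                    if t not in self.treatments:
                        raise ConfigError(
                            f"indicator {name!r}: effect for unknown treatment {t!r}")
        for var, per_treatment in self.yield_root_specs.items():
            for t in per_treatment:
                if t not in self.treatments:
                    raise ConfigError(
                        f"variable {var!r}: spec for unknown treatment {t!r}")
        if self.community_spec is not None:
            cs = self.community_spec
            if cs.concentration <= 0:
                raise ConfigError("Dirichlet concentration must be > 0")
            if cs.reads_per_sample <= 0:
                raise ConfigError("reads_per_sample must be > 0")
            for depth, vec in cs.baseline.items():
                total = sum(vec.values())
                if abs(total - 1.0) > 1e-9:
                    raise ConfigError(
                        f"community baseline for depth {depth!r} sums to {total}, not 1")
            for depth, phyla in cs.fold_changes.items():
                for ph, folds in phyla.items():
                    for t in folds:
                        if t not in self.treatments:
                            raise ConfigError(
                                f"community fold change for unknown treatment {t!r}")

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


def default_config(seed: int = 42) -> GeneratorConfig:
    return GeneratorConfig(seed=seed)


def null_config(seed: int = 42) -> GeneratorConfig:
    """A trial with no treatment or depth effects on soil variables.

    Every effect multiplier is 1, so all indicators and enzymes vary
    independently around their CK means.  Used for calibration and power
    studies where a known signal is injected afterwards.
    """
    cfg = GeneratorConfig(seed=seed, community_spec=None)
    for spec in {**cfg.indicator_specs, **cfg.enzyme_specs}.values():
        spec.effects = {d: _flat() for d in cfg.depths}
    return cfg


@dataclass
class TrialDataset:
    """Plot-level observations in long format, plus optional community."""

    records: pd.DataFrame  # columns: treatment, replicate, depth, variable, value, unit
    community: CommunityTable | None = None

    def validate(self) -> None:
        keys = self.records[["treatment", "replicate", "depth", "variable"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate observation key: {dup}")
        cell_sizes = (
            self.records.groupby(["variable", "depth"])["replicate"]
            .count()
            .groupby(level="variable")
            .nunique()
        )
        per_cell = self.records.groupby(["variable", "depth", "treatment"]).size()
        if per_cell.groupby(level=["variable", "depth"]).nunique().gt(1).any():
            raise ValueError("unbalanced design: unequal replicate counts per cell")
        if (self.records["value"] < 0).any():
            bad = self.records[self.records["value"] < 0].iloc[0]
            raise ValueError(
                f"negative value for {bad['variable']} at "
                f"({bad['treatment']}, {bad['replicate']}, {bad['depth']})")
        _ = cell_sizes

    def to_wide(self) -> pd.DataFrame:
        """Samples x variables table indexed by (treatment, replicate, depth)."""
        return self.records.pivot_table(
            index=["treatment", "replicate", "depth"],
            columns="variable",
            values="value",
            aggfunc="first",
            observed=True,
        )

    def variables(self) -> list[str]:
        return sorted(self.records["variable"].unique())


def _draw(rng, mean: float, sd: float, shared: float, rho: float) -> float:
    """One truncated-normal draw with optional shared-latent correlation."""
    eps = rng.standard_normal()
    z = np.sqrt(1.0 - rho) * eps + np.sqrt(rho) * shared
    return max(0.0, mean + sd * z)


def generate_trial(
    config: GeneratorConfig, *, include_community: bool = True
) -> TrialDataset:
    """Generate one balanced synthetic trial dataset.

    Reproducible: the same config (including seed) always yields the same
    dataset.  Soil indicators and enzymes are generated per treatment x
    replicate x depth; yield and root traits per treatment x replicate at
    the plot level (depth label ``"plot"``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rho = config.indicator_correlation
    rows = []

    block_effects = {
        r: (config.block_sd * rng.standard_normal() if config.block_sd > 0 else 0.0)
        for r in range(1, config.replicates + 1)
    }

    # one shared latent normal per sample drives optional cross-indicator
    # correlation; drawn up front so variable order cannot matter
    shared = {
        (t, r, d): rng.standard_normal()
        for t in config.treatments
        for r in range(1, config.replicates + 1)
        for d in config.depths
    }
    shared_plot = {
        (t, r): rng.standard_normal()
        for t in config.treatments
        for r in range(1, config.replicates + 1)
    }

    for name, spec in {**config.indicator_specs, **config.enzyme_specs}.items():
        for depth in config.depths:
            effects = spec.effects.get(depth, {})
            for t in config.treatments:
                mean = spec.ck_mean[depth] * effects.get(t, 1.0)
                sd = spec.cv * mean
                for r in range(1, config.replicates + 1):
                    value = _draw(rng, mean * (1.0 + block_effects[r]), sd,
                                  shared[(t, r, depth)], rho)
                    rows.append((t, r, depth, name, value, spec.unit))

    for var, per_treatment in config.yield_root_specs.items():
        unit = YIELD_ROOT_UNITS.get(var, "")
        for t in config.treatments:
            mean, sd = per_treatment[t]
            for r in range(1, config.replicates + 1):
                value = _draw(rng, mean * (1.0 + block_effects[r]), sd,
                              shared_plot[(t, r)], rho)
                rows.append((t, r, "plot", var, value, unit))

    records = pd.DataFrame(
        rows, columns=["treatment", "replicate", "depth", "variable", "value", "unit"]
    )
    community = None
    if include_community and config.community_spec is not None:
        community = generate_community(config)
    dataset = TrialDataset(records=records, community=community)
    dataset.validate()
    return dataset


def generate_community(config: GeneratorConfig) -> CommunityTable:
    """Generate the taxon x sample count table for one trial.

    Per sample, phylum proportions are drawn from
    Dirichlet(concentration x mean vector) and read counts from a
    multinomial at the configured sequencing depth.  Each phylum is split
    into a fixed number of taxa with phylum-internal weights drawn once
    per trial, and the taxon -> phylum map is emitted alongside.

    Uses a sub-stream of the trial seed, so trial values and community
    counts are independently reproducible.
    """
    config.validate()
    cs = config.community_spec
    if cs is None:
        raise ConfigError("community_spec absent")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    phyla = list(cs.baseline[config.depths[0]])
    taxa, taxon_phylum = [], {}
    within: dict[str, np.ndarray] = {}
    for ph in phyla:
        w = rng.dirichlet(np.full(cs.taxa_per_phylum, 5.0))
        within[ph] = w
        for i in range(cs.taxa_per_phylum):
            taxon = f"{ph}_OTU{i + 1}"
            taxa.append(taxon)
            taxon_phylum[taxon] = ph

    columns, meta_rows = {}, []
    for t in config.treatments:
        for d in config.depths:
            mean_vec = cs.mean_vector(t, d).reindex(phyla)
            alpha = cs.concentration * mean_vec.to_numpy()
            for r in range(1, config.replicates + 1):
                sample = f"{t}_r{r}_{d}"
                props = rng.dirichlet(alpha)
                taxon_probs = np.concatenate(
                    [p * within[ph] for p, ph in zip(props, phyla)]
                )
                counts = rng.multinomial(cs.reads_per_sample, taxon_probs)
                columns[sample] = counts
                meta_rows.append(
                    {"sample": sample, "treatment": t, "replicate": r, "depth": d}
                )

    counts = pd.DataFrame(columns, index=pd.Index(taxa, name="taxon"))
    metadata = pd.DataFrame(meta_rows).set_index("sample")
    return CommunityTable(counts=counts, taxon_phylum=taxon_phylum, metadata=metadata)
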