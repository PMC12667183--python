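"""Table readers/writers, pipeline configuration and the run-all driver.

The single interchange format is RFC-4180 CSV (UTF-8, "." decimal).
Trial observations travel in long format (treatment, replicate, depth,
variable, value, unit); wide-format tables (one column per variable) are
auto-detected on read.  Depth labels are normalised to the ASCII forms
"0-20" / "20-40".

``run_all`` executes the full analysis end to end on either a generated
or an ingested dataset and writes every stage's output plus a manifest
(seed, package version, config hash).  Identical manifest inputs yield
byte-identical output directories.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import design as design_mod
from . import soil_quality as sq
from .community import CommunityTable, bray_curtis, permanova, relative_abundance, simpson_index
from .drivers import driver_report
from .group_stats import GroupSummary, anova_from_raw, format_p, tukey_letters, two_way_anova
from .stoichiometry import panel_from_dataset
from .synthetic import ConfigError, GeneratorConfig, TrialDataset, default_config, generate_trial

__all__ = [
    "PipelineConfig",
    "read_trial_table",
    "write_trial_table",
    "read_community",
    "write_community",
    "run_all",
    "ARTIFACTS",
]

logger = logging.getLogger("manuresub")

LONG_COLUMNS = ["treatment", "replicate", "depth", "variable", "value"]
KEY_COLUMNS = ["treatment", "replicate", "depth"]

#: Canonical depth-label spellings (en-dash and unicode variants collapse
#: onto the ASCII forms).
_DEPTH_ALIASES = {
    "0–20": "0-20", "0—20": "0-20", "0-20 cm": "0-20",
    "20–40": "20-40", "20—40": "20-40", "20-40 cm": "20-40",
}


def normalize_depth(label: str) -> str:
    return _DEPTH_ALIASES.get(str(label).strip(), str(label).strip())


def read_trial_table(path, dialect: str = "auto") -> TrialDataset:
    """Read a trial observation table, auto-detecting long or wide layout.

    Long layout needs columns treatment, replicate, depth, variable,
    value (unit optional); wide layout needs treatment, replicate, depth
    plus one numeric column per variable.  Duplicate observation keys and
    non-numeric values are rejected with the offending key or row named.
    """
    path = Path(path)
    table = pd.read_csv(path)
    cols = set(table.columns)
    missing_keys = [c for c in KEY_COLUMNS if c not in cols]
    if missing_keys:
        raise ValueError(f"{path.name}: missing required column(s) {missing_keys}")

    is_long = dialect == "long" or (
        dialect == "auto" and {"variable", "value"} <= cols
    )
    if is_long:
        missing = [c for c in LONG_COLUMNS if c not in cols]
        if missing:
            raise ValueError(f"{path.name}: missing required column(s) {missing}")
        if "unit" not in cols:
            table["unit"] = ""
        long = table[LONG_COLUMNS + ["unit"]].copy()
    else:
        value_cols = [c for c in table.columns if c not in KEY_COLUMNS]
        if not value_cols:
            raise ValueError(f"{path.name}: no variable columns found")
        long = table.melt(
            id_vars=KEY_COLUMNS, value_vars=value_cols,
            var_name="variable", value_name="value",
        )
        long["unit"] = ""

    long["depth"] = long["depth"].map(normalize_depth)
    numeric = pd.to_numeric(long["value"], errors="coerce")
    bad = long[numeric.isna() & long["value"].notna()]
    if not bad.empty:
        row = bad.index[0]
        raise ValueError(
            f"{path.name}: non-numeric value {bad.loc[row, 'value']!r} at row {row + 2}"
        )
    long["value"] = numeric
    long = long.dropna(subset=["value"]).reset_index(drop=True)

    keys = long[["treatment", "replicate", "depth", "variable"]]
    dup = keys[keys.duplicated()]
    if not dup.empty:
        raise ValueError(
            f"{path.name}: duplicate observation key {dup.iloc[0].tolist()}"
        )
    dataset = TrialDataset(records=long)
    dataset.validate()
    return dataset


def write_trial_table(dataset: TrialDataset, path) -> None:
    dataset.records.to_csv(path, index=False, lineterminator="\n")


def write_community(table: CommunityTable, counts_path, map_path) -> None:
    table.counts.to_csv(counts_path, index_label="taxon", lineterminator="\n")
    pd.Series(table.taxon_phylum, name="phylum").rename_axis("taxon").to_csv(
        map_path, lineterminator="\n"
    )


def read_community(counts_path, map_path, metadata: pd.DataFrame | None = None) -> CommunityTable:
    counts = pd.read_csv(counts_path, index_col="taxon")
    phylum = pd.read_csv(map_path, index_col="taxon")["phylum"].to_dict()
    if metadata is None:
        metadata = _metadata_from_sample_names(counts.columns)
    return CommunityTable(counts=counts, taxon_phylum=phylum, metadata=metadata)


def _metadata_from_sample_names(samples) -> pd.DataFrame:
    rows = []
    for s in samples:
        parts = str(s).split("_")
        if len(parts) == 3 and parts[1].startswith("r"):
            rows.append({"sample": s, "treatment": parts[0],
                         "replicate": int(parts[1][1:]), "depth": parts[2]})
        else:
            rows.append({"sample": s, "treatment": s, "replicate": 1, "depth": ""})
    return pd.DataFrame(rows).set_index("sample")


# ------------------------------------------------------------- pipeline


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings."""

    simulate: bool = True
    input_path: str | None = None  # long/wide trial CSV when not simulating
    community_counts: str | None = None
    community_map: str | None = None
    out_dir: str = "manuresub_out"
    seed: int | None = 42
    alpha: float = 0.05
    indicators: tuple[str, ...] = sq.DEFAULT_INDICATORS
    directions: dict[str, str] | None = None
    letters_method: str = "tukey"
    n_perm: int = 999
    n_null: int = 100
    n_trees: int = 100
    reference: str = "CK"

    def validate(self) -> None:
        if not 0.0 < self.alpha <= 0.5:
            raise ConfigError(f"alpha must be in (0, 0.5], got {self.alpha}")
        if self.seed is None and (self.n_perm > 0 or self.n_null > 0):
            raise ConfigError("a seed is mandatory when permutations are requested")
        if not self.simulate and self.input_path is None:
            raise ConfigError("either simulate=True or an input path is required")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**mapping)
        if isinstance(cfg.indicators, list):
            cfg.indicators = tuple(cfg.indicators)
        return cfg


def _config_hash(config: PipelineConfig) -> str:
    fields = asdict(config)
    fields.pop("out_dir", None)  # where outputs land does not change them
    payload = json.dumps(fields, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


#: The canonical output artifacts of a full run.
ARTIFACTS = (
    "trial_long.csv",
    "design.csv",
    "anova.csv",
    "sqi.csv",
    "vectors.csv",
    "community_diversity.csv",
    "drivers_importance.csv",
)


def _stage(name):
    """Log a stage with wall time; any failure is re-raised with the stage
    name attached so partial runs can be diagnosed."""
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %s: done in %.2fs", name, dt)
                return False
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return _Ctx()


def run_all(config: PipelineConfig) -> dict:
    """Execute the full analysis and write all artifacts to ``out_dir``.

    Stages: simulate/ingest -> design table -> treatment statistics ->
    SQI -> stoichiometry vectors -> community summaries -> driver
    analysis -> manifest.  Returns a dict of the in-memory results.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    with _stage("ingest"):
        if config.simulate:
            gen = default_config(seed=int(config.seed))
            dataset = generate_trial(gen)
        else:
            dataset = read_trial_table(config.input_path)
            if config.community_counts and config.community_map:
                dataset.community = read_community(
                    config.community_counts, config.community_map
                )
        write_trial_table(dataset, out / "trial_long.csv")
        results["dataset"] = dataset

    with _stage("design"):
        table = design_mod.canonical_table()
        table.to_csv(out / "design.csv", index=False, lineterminator="\n")
        results["design"] = table

    with _stage("stats"):
        rows = []
        wide = dataset.to_wide()
        for variable in dataset.variables():
            depths = dataset.records.loc[
                dataset.records["variable"] == variable, "depth"
            ].unique()
            for depth in depths:
                res = anova_from_raw(dataset, variable, depth)
                sub = wide.xs(depth, level="depth")[variable]
                groups = {t: g.to_numpy() for t, g in sub.groupby(level="treatment", sort=False)}
                letters = tukey_letters(
                    GroupSummary.from_raw(groups),
                    alpha=config.alpha, method=config.letters_method,
                )
                rows.append({
                    "variable": variable, "depth": depth, "F": res.F,
                    "df_between": res.df_between, "df_within": res.df_within,
                    "p": res.p, "p_formatted": format_p(res.p),
                    "letters": ";".join(f"{k}:{v}" for k, v in letters.items()),
                })
        anova_table = pd.DataFrame(rows)
        # two-way treatment x depth ANOVA for depth-stratified variables
        two_way_rows = []
        depth_vars = dataset.records[dataset.records["depth"] != "plot"]["variable"].unique()
        for variable in sorted(depth_vars):
            tw = two_way_anova(
                TrialDataset(records=dataset.records[dataset.records["depth"] != "plot"]),
                variable,
            )
            for term in ("treatment", "depth", "treatment:depth"):
                two_way_rows.append({
                    "variable": variable, "term": term,
                    "F": tw.loc[term, "F"], "p": tw.loc[term, "p"],
                })
        anova_table.to_csv(out / "anova.csv", index=False, lineterminator="\n")
        pd.DataFrame(two_way_rows).to_csv(
            out / "anova_two_way.csv", index=False, lineterminator="\n"
        )
        results["anova"] = anova_table

    with _stage("sqi"):
        sqi_results = sq.sqi_pipeline(
            dataset, indicators=config.indicators,
            directions=config.directions, reference=config.reference,
        )
        frames = []
        for depth, res in sqi_results.items():
            frame = res.sqi.reset_index()
            frame.insert(0, "depth", depth)
            frames.append(frame)
        pd.concat(frames).to_csv(out / "sqi.csv", index=False, lineterminator="\n")
        results["sqi"] = sqi_results

    with _stage("stoich"):
        vectors = panel_from_dataset(dataset)
        vectors.to_csv(out / "vectors.csv", index=False, lineterminator="\n")
        results["vectors"] = vectors

    with _stage("community"):
        if dataset.community is not None:
            comm = dataset.community
            rel = relative_abundance(comm, level="phylum")
            rel.to_csv(out / "community_phylum.csv",
                       index_label="phylum", lineterminator="\n")
            diversity = pd.DataFrame({
                "sample": comm.samples,
                "simpson": [simpson_index(comm.counts[s]) for s in comm.samples],
            })
            diversity.to_csv(out / "community_diversity.csv",
                             index=False, lineterminator="\n")
            dm = bray_curtis(comm)
            dm.to_csv(out / "community_braycurtis.csv", lineterminator="\n")
            perm_rows = []
            for depth in comm.metadata["depth"].unique():
                samples = comm.metadata.index[comm.metadata["depth"] == depth]
                res = permanova(
                    dm.loc[samples, samples],
                    comm.metadata.loc[samples, "treatment"],
                    n_perm=config.n_perm, seed=config.seed,
                )
                perm_rows.append({"depth": depth, "pseudo_F": res.pseudo_f, "p": res.p})
            pd.DataFrame(perm_rows).to_csv(
                out / "community_permanova.csv", index=False, lineterminator="\n"
            )
            results["community"] = {"relative_abundance": rel, "diversity": diversity,
                                    "braycurtis": dm, "permanova": perm_rows}
        else:
            # keep the artifact set complete even without community data
            pd.DataFrame(columns=["sample", "simpson"]).to_csv(
                out / "community_diversity.csv", index=False, lineterminator="\n"
            )

    with _stage("drivers"):
        report = driver_report(
            dataset, results["vectors"], results["sqi"],
            n_perm=config.n_perm, n_null=config.n_null,
            n_trees=config.n_trees, seed=config.seed,
        )
        imp_frames, corr_frames = [], []
        for depth, per_resp in report.items():
            for resp, tables in per_resp.items():
                imp = tables["importance"].reset_index(names="feature")
                imp.insert(0, "response", resp)
                imp.insert(0, "depth", depth)
                imp_frames.append(imp)
                corr = tables["correlations"].reset_index()
                corr.insert(0, "response", resp)
                corr.insert(0, "depth", depth)
                corr_frames.append(corr)
        pd.concat(imp_frames).to_csv(
            out / "drivers_importance.csv", index=False, lineterminator="\n"
        )
        pd.concat(corr_frames).to_csv(
            out / "drivers_correlations.csv", index=False, lineterminator="\n"
        )
        results["drivers"] = report

    with _stage("manifest"):
        from importlib.metadata import version

        try:
            pkg_version = version("manuresub")
        except Exception:
            pkg_version = "unknown"
        manifest = {
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "package_version": pkg_version,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "artifacts": sorted(p.name for p in out.iterdir() if p.suffix == ".csv"),
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        results["manifest"] = manifest

    return results
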