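"""End-to-end orchestration: config, analysis sequencing and table output.

``run_pipeline`` takes a validated :class:`PipelineConfig`, loads (or
simulates) an occurrence dataset, and emits the analysis surfaces as CSV
tables: richness per wave plus trend tests, per-region shift summaries
(grand-mean and elevation-corrected), the cross-region mixed models, and one
null-model comparison table per requested variant, together with the filter
exclusion report and a run manifest. All file writes are atomic
(write-to-temp, then rename); per-region failures are isolated and reported
so the remaining regions still complete.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .limits import compute_shifts, records_frame, standardize
from .models import cross_region_mean_shift, elevation_corrected_shift, elevation_dependence, mean_shift
from .nullmodel import NullConfig, build_envelope, compare_to_null, observed_fit_for_region
from .richness import percent_trend_test, richness_frame, richness_table, richness_trend_test
from .simulate import SyntheticParams, generate_design, generate_spread_dataset, write_truth_csv
from .survey import (
    apply_filters,
    collapse_to_presence,
    design_from_records,
    read_occurrences,
)

logger = logging.getLogger(__name__)

_VALID_FILTERS = ("singleton", "f1", "f2", "f3")
_VALID_VARIANTS = ("surveyed", "grid200", "observed_initials")

_CONFIG_KEYS = {
    "input",
    "schema",
    "synthetic",
    "filter",
    "distance_classes",
    "variants",
    "n_boot",
    "seed",
    "out",
    "annualize",
    "use_second_wave",
    "x_eval",
    "figures",
}


@dataclass
class PipelineConfig:
    """Validated settings of one pipeline run."""

    input: str | None = None
    schema: dict = field(default_factory=dict)
    synthetic: SyntheticParams | None = None
    filter_id: str = "singleton"
    distance_classes: list[int] | None = None
    variants: list[str] = field(default_factory=lambda: ["surveyed"])
    n_boot: int = 10_000
    seed: int = 0
    out: str = "upslope_out"
    annualize: bool = False
    use_second_wave: bool = False  # compare t2 - t1 instead of tlast - t1
    x_eval: str = "gradient_median"  # or "species_median"
    figures: bool = False

    def validate(self) -> None:
        if (self.input is None) == (self.synthetic is None):
            raise ValueError("exactly one of 'input' and 'synthetic' must be set")
        if self.filter_id not in _VALID_FILTERS:
            raise ValueError(f"unknown filter {self.filter_id!r}; use one of {_VALID_FILTERS}")
        for v in self.variants:
            if v not in _VALID_VARIANTS:
                raise ValueError(f"unknown null variant {v!r}; use one of {_VALID_VARIANTS}")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.x_eval not in ("gradient_median", "species_median"):
            raise ValueError("x_eval must be 'gradient_median' or 'species_median'")


def validate_config(path: str | Path, **overrides) -> PipelineConfig:
    """Load and validate a YAML config file; keyword overrides win."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    synthetic = raw.get("synthetic")
    cfg = PipelineConfig(
        input=raw.get("input"),
        schema=raw.get("schema") or {},
        synthetic=SyntheticParams(**synthetic) if isinstance(synthetic, dict) else synthetic,
        filter_id=raw.get("filter", "singleton"),
        distance_classes=raw.get("distance_classes"),
        variants=list(raw.get("variants", ["surveyed"])),
        n_boot=int(raw.get("n_boot", 10_000)),
        seed=int(raw.get("seed", 0)),
        out=str(raw.get("out", "upslope_out")),
        annualize=bool(raw.get("annualize", False)),
        use_second_wave=bool(raw.get("use_second_wave", False)),
        x_eval=raw.get("x_eval", "gradient_median"),
        figures=bool(raw.get("figures", False)),
    )
    cfg.validate()
    return cfg


def _atomic_write(df: pd.DataFrame, path: Path) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    os.close(fd)
    try:
        df.to_csv(tmp, index=False)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _atomic_write_json(obj, path: Path) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    os.close(fd)
    try:
        with open(tmp, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _load(config: PipelineConfig):
    """Returns (tables, design, truth_or_None)."""
    if config.synthetic is not None:
        params = config.synthetic
        design = generate_design(params)
        tables, truth = generate_spread_dataset(design, params)
        return tables, design, truth
    records = read_occurrences(config.input, schema=config.schema)
    design = design_from_records(records)
    tables = collapse_to_presence(records, distance_classes=config.distance_classes)
    return tables, design, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the output bundle as in-memory objects.

    Writes under ``config.out``: richness.csv, richness_trends.csv,
    shift_records.csv, region_shifts.csv, cross_region_models.csv,
    null_comparison.csv, exclusions.csv, manifest.json (plus
    synthetic_truth.csv for simulated inputs and PNG figures when enabled).
    """
    config.validate()
    out_dir = Path(config.out)
    out_dir.mkdir(parents=True, exist_ok=True)

    tables, design, truth = _load(config)

    # richness trends always use the singleton-filtered dataset
    singleton_tables, _ = apply_filters(tables, "singleton")
    rich_records = richness_table(singleton_tables)
    rich_df = richness_frame(rich_records)
    trend_rows = []
    for name, runner in (
        ("richness", richness_trend_test),
        ("percent_change", percent_trend_test),
    ):
        try:
            test = runner(rich_records)
        except ValueError as exc:  # e.g. a single region: no cross-region trend
            logger.warning("richness trend %s skipped: %s", name, exc)
            trend_rows.append({"response": name, "error": str(exc)})
            continue
        trend_rows.append(
            {
                "response": name,
                "slope": test.slope,
                "se": test.se,
                "chi2": test.chi2,
                "p": test.p,
                "n": test.n,
                "n_regions": test.n_regions,
                "singular": test.singular,
            }
        )

    filtered, exclusions = apply_filters(tables, config.filter_id)

    regions = sorted({region for region, _ in filtered})
    standardizers = {}
    all_records = []
    region_rows = []
    null_rows = []
    failures = []
    envelopes = {}
    for region in regions:
        try:
            years = sorted(year for reg, year in filtered if reg == region)
            rd = design[region]
            last_idx = 1 if (config.use_second_wave and len(years) > 2) else len(years) - 1
            first = filtered[(region, years[0])]
            last = filtered[(region, years[last_idx])]
            interval = years[last_idx] - years[0]
            records = compute_shifts(first, last, interval)
            if len(records) < 3:
                raise ValueError(f"only {len(records)} species with shifts in {region}")
            all_records.extend(records)
            _, std = standardize(rd.elevations, region)
            standardizers[region] = std

            est, (lo, hi), _ = mean_shift(records, annualize=config.annualize)
            if config.x_eval == "gradient_median":
                x_eval = float(np.median(rd.elevations))
            else:
                x_eval = float(np.median([r.limit_t1 for r in records]))
            cest, (clo, chi_), slope_fit = elevation_corrected_shift(
                records, x_eval, bounds=rd.bounds, annualize=config.annualize
            )
            region_rows.append(
                {
                    "region": region,
                    "n_species": len(records),
                    "interval_years": interval,
                    "mean_shift": est,
                    "mean_shift_lo": lo,
                    "mean_shift_hi": hi,
                    "corrected_shift": cest,
                    "corrected_shift_lo": clo,
                    "corrected_shift_hi": chi_,
                    "x_eval": x_eval,
                    "slope": slope_fit.slope,
                    "slope_se": slope_fit.se_slope,
                }
            )

            obs_fit = observed_fit_for_region(records)
            for variant in config.variants:
                ncfg = NullConfig(
                    variant=variant,
                    n_boot=config.n_boot,
                    seed=config.seed,
                    bounds=rd.bounds,
                )
                env = build_envelope(records, ncfg, design=design, region=region)
                comp = compare_to_null(obs_fit, env)
                envelopes[(region, variant)] = (records, obs_fit, env, comp)
                null_rows.append(
                    {
                        "region": region,
                        "variant": variant,
                        "n_boot": config.n_boot,
                        "seed": config.seed,
                        "prop_above": comp.prop_above,
                        "prop_below": comp.prop_below,
                        "significant": comp.significant,
                        "above_ranges": ";".join(f"{a:.1f}-{b:.1f}" for a, b in comp.above_ranges),
                        "below_ranges": ";".join(f"{a:.1f}-{b:.1f}" for a, b in comp.below_ranges),
                    }
                )
        except Exception as exc:  # noqa: BLE001 - isolate per-region failures
            logger.exception("region %s failed", region)
            failures.append({"region": region, "error": str(exc)})

    cross_rows = []
    if len({r.region for r in all_records}) >= 2:
        cm = cross_region_mean_shift(all_records, standardizers=standardizers)
        cross_rows.append(
            {
                "model": "grand_mean",
                "estimate": cm.estimate,
                "se": cm.se,
                "t": cm.t,
                "df": cm.df,
                "p": cm.p,
                "slope": np.nan,
                "slope_se": np.nan,
                "f": np.nan,
                "n": cm.n,
                "n_regions": cm.n_regions,
            }
        )
        ed, per_region_slopes = elevation_dependence(all_records, standardizers=standardizers)
        cross_rows.append(
            {
                "model": "elevation_dependence",
                "estimate": ed.estimate,
                "se": ed.se,
                "t": ed.slope_t,
                "df": ed.slope_df,
                "p": ed.slope_p,
                "slope": ed.slope,
                "slope_se": ed.slope_se,
                "f": ed.f_statistic,
                "n": ed.n,
                "n_regions": ed.n_regions,
            }
        )
    else:
        per_region_slopes = pd.DataFrame()

    shift_df = records_frame(all_records)
    region_df = pd.DataFrame(region_rows)
    null_df = pd.DataFrame(null_rows)
    cross_df = pd.DataFrame(cross_rows)
    failure_df = pd.DataFrame(failures, columns=["region", "error"])

    _atomic_write(rich_df, out_dir / "richness.csv")
    _atomic_write(pd.DataFrame(trend_rows), out_dir / "richness_trends.csv")
    _atomic_write(shift_df, out_dir / "shift_records.csv")
    _atomic_write(region_df, out_dir / "region_shifts.csv")
    _atomic_write(cross_df, out_dir / "cross_region_models.csv")
    _atomic_write(null_df, out_dir / "null_comparison.csv")
    _atomic_write(exclusions, out_dir / "exclusions.csv")
    _atomic_write(failure_df, out_dir / "failures.csv")
    if truth is not None:
        write_truth_csv(truth, out_dir / "synthetic_truth.csv")

    cfg_dict = asdict(config)
    if config.synthetic is not None:
        cfg_dict["synthetic"] = asdict(config.synthetic) if not callable(
            getattr(config.synthetic, "spread_rate", None)
        ) else "custom"
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    from . import __version__ as pkg_version

    manifest = {
        "package_version": pkg_version,
        "seed": config.seed,
        "config": cfg_dict if not isinstance(cfg_dict.get("synthetic"), str) else cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_regions_analysed": len(region_rows),
        "n_regions_failed": len(failures),
    }
    _atomic_write_json(manifest, out_dir / "manifest.json")

    if config.figures:
        _write_figures(envelopes, out_dir)

    return {
        "richness": rich_df,
        "richness_trends": pd.DataFrame(trend_rows),
        "shift_records": shift_df,
        "region_shifts": region_df,
        "cross_region_models": cross_df,
        "per_region_slopes": per_region_slopes,
        "null_comparison": null_df,
        "exclusions": exclusions,
        "failures": failure_df,
        "manifest": manifest,
        "truth": truth,
    }


def _write_figures(envelopes, out_dir: Path) -> None:
    """Optional shift-vs-initial-limit panels with null envelopes (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for (region, variant), (records, obs_fit, env, comp) in envelopes.items():
        fig, ax = plt.subplots(figsize=(5, 4))
        x = [r.limit_t1 for r in records]
        y = [r.shift for r in records]
        w = np.log([r.weight for r in records])
        ax.scatter(x, y, c=w, cmap="Greys", edgecolor="k", s=25, zorder=3)
        ax.plot(env.grid, obs_fit.predict(env.grid), color="crimson", lw=2, label="observed fit")
        ax.plot(env.grid, env.mean_expected, color="grey", lw=1, label="null mean")
        ax.plot(env.grid, env.lower, "k--", lw=1)
        ax.plot(env.grid, env.upper, "k--", lw=1, label="null 95% envelope")
        ax.axhline(0.0, color="0.8", lw=0.8)
        ax.set_xlabel("upper limit at first survey (m)")
        ax.set_ylabel("shift in upper limit (m)")
        ax.set_title(f"{region} ({variant}): above {comp.prop_above:.2f}, below {comp.prop_below:.2f}")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out_dir / f"null_{region}_{variant}.png", dpi=150)
        plt.close(fig)
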