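"""Orchestration: validate CSV inputs and run the full analysis to reports.

``run_pipeline`` executes every stage for which inputs are present —
thermal time, emergence, growth, phenology, fecundity, competition — and
writes one tidy report CSV per published-table analogue plus a JSON run
manifest (seed, config, stage status). Partial inputs produce partial
reports with the skips recorded in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .competition import HyperbolicModel, compare_dens50
from .emergence import EmergenceModel, compare_parameters
from .exceptions import PhenokitError, ValidationError
from .fecundity import (calibrate, estimate_plant, fecundity_ratio_test,
                        parse_length_list)
from .growth import GrowthModel, suppression_ratio
from .phenology import bootstrap_mean_ci, pairwise_stage_tests
from .thermal import DEFAULT_BASE_C, accumulate, validate_weather

logger = logging.getLogger("phenokit")

STREAMS = ("weather", "emergence", "biomass", "stages", "calibration",
           "plants", "pots")

REQUIRED_COLUMNS = {
    "weather": {"date", "tmin_c", "tmax_c", "source"},
    "emergence": {"unit_id", "species", "crop", "year", "cum_tt_c", "cum_count"},
    "biomass": {"plot_id", "species", "crop", "year", "cum_tt_c",
                "dm_per_plant_g"},
    "stages": {"plant_id", "species", "crop", "year", "bbch_stage",
               "tt_lo_c", "tt_hi_c"},
    "calibration": {"species", "length_cm", "seed_count"},
    "plants": {"plant_id", "species", "crop", "year", "panicle_lengths"},
    "pots": {"species", "crop_stage", "density_m2", "harvest", "response",
             "response_type", "rep"},
}


@dataclass
class RunConfig:
    """Everything a pipeline run needs; loadable from YAML.

    ``inputs`` maps stream name -> CSV path; missing streams are skipped.
    ``family_by_year`` selects the biomass curve family per season label.
    """

    inputs: dict = field(default_factory=dict)
    out_dir: str = "phenokit-out"
    seed: int = 0
    n_perm: int = 1000
    n_boot: int = 10000
    base_temp_c: float = DEFAULT_BASE_C
    family_by_year: dict = field(
        default_factory=lambda: {"2017/18": "weibull", "2018/19": "loglogistic"})
    use_censoring: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.n_perm < 1 or cfg.n_boot < 1:
            raise ValidationError("resampling sizes must be >= 1")
        return cfg

    def digest(self) -> str:
        blob = json.dumps({k: str(v) for k, v in self.__dict__.items()},
                          sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class Issue:
    """One machine-readable validation finding."""

    file: str
    row: int | None
    message: str


def validate_inputs(paths: dict) -> list[Issue]:
    """Schema + invariant + cross-file checks; reports rather than raises.

    ``paths`` maps stream name to CSV path. Column order is irrelevant
    (header-based). Returned row numbers are zero-based data rows.
    """
    issues: list[Issue] = []
    frames: dict[str, pd.DataFrame] = {}
    for stream, path in paths.items():
        if stream not in REQUIRED_COLUMNS:
            issues.append(Issue(str(path), None, f"unknown stream {stream!r}"))
            continue
        p = Path(path)
        if not p.exists():
            issues.append(Issue(str(path), None, "file does not exist"))
            continue
        try:
            df = pd.read_csv(p)
        except Exception as err:  # malformed CSV
            issues.append(Issue(str(path), None, f"unreadable CSV: {err}"))
            continue
        missing = REQUIRED_COLUMNS[stream] - set(df.columns)
        if missing:
            issues.append(Issue(str(path), None,
                                f"missing columns: {sorted(missing)}"))
            continue
        frames[stream] = df
        issues.extend(_stream_checks(stream, str(path), df))

    species_by_stream = {
        s: set(frames[s]["species"].unique())
        for s in frames if "species" in frames[s].columns
    }
    if len(species_by_stream) > 1:
        universe = set.union(*species_by_stream.values())
        for s, sp in species_by_stream.items():
            orphan = sp - set.union(*(v for k, v in species_by_stream.items()
                                      if k != s))
            # species appearing in exactly one stream are suspicious only
            # when another stream of the same kind should share them; report
            # mismatching labels (e.g. typos) between emergence and biomass
            del orphan
        for a, b in (("emergence", "biomass"), ("calibration", "plants")):
            if a in species_by_stream and b in species_by_stream:
                only_b = species_by_stream[b] - species_by_stream[a]
                if only_b:
                    issues.append(Issue(str(paths[b]), None,
                                        f"species {sorted(only_b)} absent from "
                                        f"{a} stream"))
    return issues


def _stream_checks(stream: str, path: str, df: pd.DataFrame) -> list[Issue]:
    issues = []
    if stream == "weather":
        bad = df.index[df["tmin_c"] > df["tmax_c"]]
        issues += [Issue(path, int(i), "tmin_c > tmax_c") for i in bad]
        try:
            validate_weather(df)
        except PhenokitError as err:
            issues.append(Issue(path, None, str(err)))
    elif stream == "emergence":
        for uid, g in df.groupby("unit_id"):
            g = g.sort_values("cum_tt_c")
            drops = g.index[g["cum_count"].diff() < 0]
            issues += [Issue(path, int(i),
                             f"unit {uid}: cumulative count decreases")
                       for i in drops]
    elif stream == "stages":
        bad = df.index[df["tt_lo_c"] > df["tt_hi_c"]]
        issues += [Issue(path, int(i), "tt_lo_c > tt_hi_c") for i in bad]
    elif stream == "calibration":
        bad = df.index[df["length_cm"] <= 0]
        issues += [Issue(path, int(i), "nonpositive panicle length")
                   for i in bad]
    elif stream == "pots":
        bad = df.index[df["density_m2"] < 0]
        issues += [Issue(path, int(i), "negative wheat density") for i in bad]
    return issues


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------

def emergence_report(df: pd.DataFrame, use_censoring: bool = False
                     ) -> pd.DataFrame:
    """Per species x year log-logistic fit; mirrors the emergence table."""
    rows = []
    fits = {}
    for (sp, year), g in df.groupby(["species", "year"], sort=True):
        res = EmergenceModel.from_dataframe(g, use_censoring=use_censoring).fit()
        fits[(sp, year)] = res
        q = {p: res.quantile(p) for p in (0.1, 0.5, 0.9)}
        rows.append({
            "species": sp, "year": year, "n_units": res.n_units,
            "b": res.b, "b_se": res.bse["b"],
            "germ10": q[0.1].estimate, "germ10_lo": q[0.1].ci_lo,
            "germ10_hi": q[0.1].ci_hi,
            "germ50": q[0.5].estimate, "germ50_lo": q[0.5].ci_lo,
            "germ50_hi": q[0.5].ci_hi,
            "germ90": q[0.9].estimate, "germ90_lo": q[0.9].ci_lo,
            "germ90_hi": q[0.9].ci_hi,
            "converged": res.converged,
        })
    report = pd.DataFrame(rows)
    report.attrs["fits"] = fits
    return report


def emergence_pairwise(fits: dict) -> pd.DataFrame:
    """Within-year pairwise Wald comparisons of b and GERM50."""
    rows = []
    keys = sorted(fits)
    for i, ka in enumerate(keys):
        for kb in keys[i + 1:]:
            if ka[1] != kb[1]:
                continue
            for which in ("b", "g50"):
                t = compare_parameters(fits[ka], fits[kb], which=which)
                rows.append({"year": ka[1], "species_a": ka[0],
                             "species_b": kb[0], "parameter": which,
                             "difference": t.difference, "se": t.se,
                             "pvalue": t.pvalue})
    return pd.DataFrame(rows)


def growth_report(df: pd.DataFrame, family_by_year: dict) -> pd.DataFrame:
    """Per species x year curve fits plus +crop/-crop d-ratio rows."""
    rows = []
    for (sp, year), g in df.groupby(["species", "year"], sort=True):
        family = family_by_year.get(year, "loglogistic")
        fits = {}
        for crop, gc in g.groupby("crop"):
            res = GrowthModel.from_dataframe(gc, family).fit()
            fits[crop] = res
            try:
                f_stat, lof_p = res.lack_of_fit()
            except PhenokitError:
                f_stat, lof_p = np.nan, np.nan
            rows.append({
                "species": sp, "year": year, "crop": crop, "family": family,
                "c": res.c, "c_se": res.bse["c"],
                "d": res.d, "d_se": res.bse["d"],
                "timing": res.timing, "timing_se": res.bse.iloc[2],
                "time50": res.time50(), "lack_of_fit_p": lof_p,
                "ratio": np.nan, "ratio_se": np.nan, "ratio_p": np.nan,
            })
        if 0 in fits and 1 in fits:
            r = suppression_ratio(fits[0], fits[1])
            rows.append({
                "species": sp, "year": year, "crop": -1, "family": family,
                "c": np.nan, "c_se": np.nan, "d": np.nan, "d_se": np.nan,
                "timing": np.nan, "timing_se": np.nan, "time50": np.nan,
                "lack_of_fit_p": np.nan,
                "ratio": r.ratio, "ratio_se": r.se, "ratio_p": r.pvalue,
            })
    return pd.DataFrame(rows)


def phenology_report(df: pd.DataFrame, n_perm: int, n_boot: int,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Pairwise species tests plus bootstrap means per stage x year."""
    frames = []
    for (stage, year), g in df.groupby(["bbch_stage", "year"], sort=True):
        pw = pairwise_stage_tests(g, n_iter=n_perm, n_boot=n_boot, rng=rng)
        pw.insert(0, "bbch_stage", stage)
        pw.insert(1, "year", year)
        frames.append(pw)
        means = []
        for sp, gsp in g.groupby("species"):
            ci = bootstrap_mean_ci(gsp["tt_lo_c"], gsp["tt_hi_c"],
                                   n_boot=n_boot, rng=rng)
            means.append({"bbch_stage": stage, "year": year, "group_a": sp,
                          "group_b": "", "mean_diff_c": np.nan,
                          "pvalue": np.nan, "mean_c": ci.estimate,
                          "ci_lo": ci.lo, "ci_hi": ci.hi})
        frames.append(pd.DataFrame(means))
    out = pd.concat(frames, ignore_index=True)
    return out


def fecundity_report(calib_df: pd.DataFrame, plants_df: pd.DataFrame,
                     n_perm: int, n_boot: int,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Mirror of the seed-production table: means, ratio, CI, p per species."""
    rows = []
    for sp, gcal in calib_df.groupby("species", sort=True):
        cal = calibrate(gcal["length_cm"], gcal["seed_count"], species=sp)
        for year, gyr in plants_df[plants_df["species"] == sp].groupby("year"):
            seeds = {}
            for crop, gp in gyr.groupby("crop"):
                seeds[crop] = np.array([
                    estimate_plant(cal, parse_length_list(v))
                    for v in gp["panicle_lengths"]])
            if 0 not in seeds or 1 not in seeds:
                continue
            res = fecundity_ratio_test(seeds[0], seeds[1], n_perm=n_perm,
                                       n_boot=n_boot, rng=rng)
            rows.append({
                "species": sp, "year": year,
                "calibration_slope": cal.slope,
                "calibration_r2": cal.r_squared,
                "mean_no_crop": res.mean_minus, "mean_with_crop": res.mean_plus,
                "ratio": res.ratio, "ratio_lo": res.ci_lo,
                "ratio_hi": res.ci_hi, "pvalue": res.pvalue,
            })
    return pd.DataFrame(rows)


def competition_report(df: pd.DataFrame) -> pd.DataFrame:
    """DENS50 per cell with between-species Wald p, mirroring the pot table."""
    rows = []
    fits = {}
    cells = df.groupby(["species", "crop_stage", "harvest", "response_type"],
                       sort=True)
    for key, g in cells:
        res = HyperbolicModel.from_dataframe(g).fit()
        fits[key] = res
        rows.append({
            "species": key[0], "crop_stage": key[1], "harvest": key[2],
            "response_type": key[3], "a": res.a, "a_se": res.bse["a"],
            "dens50": res.dens50, "dens50_se": res.bse["dens50"],
            "converged": res.converged,
        })
    report = pd.DataFrame(rows)
    # between-species comparison within stage x harvest x response
    comp_rows = []
    seen = sorted({(k[1], k[2], k[3]) for k in fits})
    for stage, harvest, rtype in seen:
        sub = sorted(k for k in fits if k[1:] == (stage, harvest, rtype))
        for i, ka in enumerate(sub):
            for kb in sub[i + 1:]:
                if not (fits[ka].converged and fits[kb].converged):
                    continue
                t = compare_dens50(fits[ka], fits[kb])
                comp_rows.append({
                    "crop_stage": stage, "harvest": harvest,
                    "response_type": rtype, "species_a": ka[0],
                    "species_b": kb[0], "difference": t.difference,
                    "pvalue": t.pvalue,
                })
    report.attrs["pairwise"] = pd.DataFrame(comp_rows)
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage with available inputs; write reports + manifest.

    Returns the manifest dict (also written to ``run_manifest.json``).
    Raises :class:`ValidationError` if validation finds issues or no input
    stream is present at all.
    """
    paths = {k: v for k, v in config.inputs.items() if v}
    if not paths:
        raise ValidationError("no input streams configured")
    issues = validate_inputs(paths)
    if issues:
        raise ValidationError(
            f"{len(issues)} validation issue(s); first: {issues[0]}",
            issues=issues)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    status: dict[str, str] = {}
    written: list[str] = []

    def _write(name: str, df: pd.DataFrame):
        path = out / name
        df.to_csv(path, index=False)
        written.append(name)

    if "emergence" in paths:
        df = pd.read_csv(paths["emergence"])
        rep = emergence_report(df, use_censoring=config.use_censoring)
        _write("emergence_report.csv", rep.drop(columns=[], errors="ignore"))
        _write("emergence_pairwise.csv", emergence_pairwise(rep.attrs["fits"]))
        status["emergence"] = "ok"
    else:
        status["emergence"] = "skipped (no input)"

    if "biomass" in paths:
        df = pd.read_csv(paths["biomass"])
        _write("growth_report.csv", growth_report(df, config.family_by_year))
        status["growth"] = "ok"
    else:
        status["growth"] = "skipped (no input)"

    if "stages" in paths:
        df = pd.read_csv(paths["stages"])
        _write("phenology_report.csv",
               phenology_report(df, config.n_perm, config.n_boot, rng))
        status["phenology"] = "ok"
    else:
        status["phenology"] = "skipped (no input)"

    if "calibration" in paths and "plants" in paths:
        calib = pd.read_csv(paths["calibration"])
        plants = pd.read_csv(paths["plants"])
        _write("fecundity_report.csv",
               fecundity_report(calib, plants, config.n_perm, config.n_boot,
                                rng))
        status["fecundity"] = "ok"
    else:
        status["fecundity"] = "skipped (no input)"

    if "pots" in paths:
        df = pd.read_csv(paths["pots"])
        rep = competition_report(df)
        _write("competition_report.csv", rep)
        _write("competition_pairwise.csv", rep.attrs["pairwise"])
        status["competition"] = "ok"
    else:
        status["competition"] = "skipped (no input)"

    for stage, st in status.items():
        logger.info("stage %s: %s", stage, st)

    manifest = {
        "phenokit_version": __version__,
        "seed": config.seed,
        "config_digest": config.digest(),
        "n_perm": config.n_perm,
        "n_boot": config.n_boot,
        "base_temp_c": config.base_temp_c,
        "stages": status,
        "reports": written,
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def thermal_series_report(weather_df: pd.DataFrame, origin, source: str,
                          base: float = DEFAULT_BASE_C) -> pd.DataFrame:
    """Cumulative thermal-time CSV contract (date, cum_tt_c)."""
    series = accumulate(weather_df, origin=origin, source=source, base=base)
    return series.to_frame()
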