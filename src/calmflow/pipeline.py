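"""End-to-end orchestration: simulate -> spectral -> comfort -> screen ->
stats -> thermography, with a structured JSON-able report.

Stage order mirrors the study's workflow; screening runs before inference
so the ANOVA sample size matches the retained cohort.  Each stage logs its
in/out counts and fails fast with a stage-named error.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .comfort import ThermalInput, comfort_score, ppd, summarize_environment
from .inference import (anova_condition_session, pearson_correlation,
                        slope_tests_by_session, two_point_slope,
                        wilcoxon_ranksum)
from .screening import (DELTA_AMPLITUDE_LIMIT_UV, apply_exclusion_rules,
                        jackknife_mahalanobis)
from .spectral import (DEFAULT_BANDS, differential_from_first,
                       electrodes_of_interest, rereference,
                       session_band_table)
from .synthetic import (CONDITIONS, SimulationConfig, generate_cohort,
                        generate_eeg_recording)
from .thermography import skin_temperature_change


class StageError(RuntimeError):
    """An error raised by a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_bins: int = 20
    alpha: float = 0.05
    clothing: float = 0.7            # clo
    metabolic_rate: float = 1.0      # met
    include_session1_in_eeg_anova: bool = True
    slope_scales: tuple[str, ...] = ("PMV", "PPD")
    screen_with_jackknife: bool = True
    thermo_ttest_mode: str = "paired"
    seed: int | None = None          # overrides simulation.seed when set

    @property
    def season(self) -> str:
        return self.simulation.season

    def config_hash(self) -> str:
        payload = json.dumps(_jsonify(vars(self)), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonify(vars(obj))
    return obj


def _stat_dict(res) -> dict:
    return _jsonify(res.to_row())


def comfort_by_condition(cohort, config: RunConfig) -> pd.DataFrame:
    """Median PMV/PPD per condition from the environmental series."""
    rows = []
    for cond, env in cohort.environment.items():
        pmvs = []
        for _, r in env.iterrows():
            inp = ThermalInput(air_temperature=r["temperature"],
                               air_velocity=r["velocity"],
                               relative_humidity=r["humidity"],
                               clothing=config.clothing,
                               metabolic_rate=config.metabolic_rate)
            pmvs.append(comfort_score(inp).pmv)
        pmvs = np.asarray(pmvs)
        rows.append({"condition": cond,
                     "pmv_median": float(np.median(pmvs)),
                     "pmv_iqr": float(np.subtract(*np.percentile(
                         pmvs, [75, 25]))),
                     "ppd_median": float(np.median([ppd(v) for v in pmvs])),
                     "n": len(pmvs)})
    return pd.DataFrame(rows).set_index("condition")


def _session_comfort_table(comfort: pd.DataFrame, sessions,
                           participants, scale: str) -> pd.DataFrame:
    """Broadcast the per-condition scale medians to participant-sessions
    (the environmental scales are condition-level measurements)."""
    col = "pmv_median" if scale == "PMV" else "ppd_median"
    rows = [(pid, cond, s, float(comfort.loc[cond, col]))
            for cond in comfort.index for s in sessions
            for pid in participants]
    return pd.DataFrame(rows, columns=["participant", "condition",
                                       "session", "value"])


def run(config: RunConfig) -> dict:
    """Execute all stages and return the report dictionary."""
    if config.seed is not None:
        config.simulation.seed = config.seed
    report: dict = {"provenance": {
        "package": "calmflow", "version": __version__,
        "seed": config.simulation.seed, "season": config.season,
        "config_hash": config.config_hash()}}
    log: list[str] = []

    # -- simulate ---------------------------------------------------------
    try:
        cohort = generate_cohort(config.simulation)
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", str(e)) from e
    n0 = config.simulation.n_participants
    log.append(f"simulate: {n0} participants x {len(CONDITIONS)} conditions")

    # -- environment + comfort -------------------------------------------
    try:
        env_summary = {cond: summarize_environment(env).to_dict()
                       for cond, env in cohort.environment.items()}
        vel_test = wilcoxon_ranksum(
            cohort.environment["AC"]["velocity"],
            cohort.environment["RS"]["velocity"])
        comfort = comfort_by_condition(cohort, config)
    except Exception as e:  # noqa: BLE001
        raise StageError("comfort", str(e)) from e
    report["environment"] = _jsonify(env_summary)
    report["environment_velocity_test"] = _stat_dict(vel_test)
    report["comfort"] = _jsonify(comfort.to_dict())

    # -- spectral ---------------------------------------------------------
    try:
        tables = []
        for rec in cohort.recordings.values():
            tables.append(session_band_table(rereference(rec),
                                             DEFAULT_BANDS, config.n_bins))
        band_table = pd.concat(tables, ignore_index=True)
        diff_table = differential_from_first(band_table)
    except Exception as e:  # noqa: BLE001
        raise StageError("spectral", str(e)) from e
    log.append(f"spectral: {len(band_table)} band-amplitude rows")

    # -- screening --------------------------------------------------------
    try:
        ttl_table = cohort.ttl_table()
        features = (band_table.groupby(["participant", "band"])["value_uV"]
                    .mean().unstack())
        candidates = None
        if config.screen_with_jackknife:
            if len(features) > features.shape[1] + 1:
                candidates = jackknife_mahalanobis(
                    features.to_numpy(), alpha=config.alpha,
                    labels=features.index.tolist())
            else:
                log.append("screen: cohort too small for the jackknife "
                           f"(n={len(features)}, p={features.shape[1]}); "
                           "rule-based screening only")
        screen = apply_exclusion_rules(
            band_table, ttl_table, config.season, candidates=candidates,
            experimenter_errors=cohort.truth["experimenter_errors"],
            participants=config.simulation.participants)
    except Exception as e:  # noqa: BLE001
        raise StageError("screen", str(e)) from e
    report["screening"] = screen.to_json_dict()
    retained = screen.retained
    log.extend(screen.log_lines())
    if not retained:
        raise StageError("screen", "empty cohort: every participant was "
                         "excluded")

    eeg_diff = diff_table[diff_table["participant"].isin(retained)]
    ttl_kept = ttl_table[ttl_table["participant"].isin(retained)]

    # -- EEG inference ----------------------------------------------------
    try:
        anova_rows = {}
        for band in ("gamma", "beta", "alpha", "theta"):
            for ch in electrodes_of_interest(band):
                sub = eeg_diff[(eeg_diff["band"] == band)
                               & (eeg_diff["channel"] == ch)]
                if not config.include_session1_in_eeg_anova:
                    sub = sub[sub["session"] > 1]
                res = anova_condition_session(sub)
                anova_rows[f"{band}:{ch}"] = {k: _stat_dict(v)
                                              for k, v in res.items()}
        sessions = sorted(ttl_table["session"].unique())
        participants = retained
        # repeated-measures correlations: band differential at each
        # electrode of interest against the session's scale value, pooled
        # over participant x condition x session points
        correlations = {}
        for scale in config.slope_scales:
            ctab = _session_comfort_table(comfort, sessions, participants,
                                          scale)
            for band in ("gamma", "beta"):
                sub = eeg_diff[eeg_diff["band"] == band]
                for ch in electrodes_of_interest(band):
                    merged = sub[sub["channel"] == ch].merge(
                        ctab, on=["participant", "condition", "session"])
                    merged = merged[merged["session"] > 1]
                    try:
                        res = pearson_correlation(merged["value"],
                                                  merged["value_uV"])
                    except ValueError:
                        continue
                    correlations[f"{band}:{ch}:{scale}"] = _stat_dict(res)
        slopes_report = {}
        for scale in config.slope_scales:
            ctab = _session_comfort_table(comfort, sessions, participants,
                                          scale)
            gamma = eeg_diff[eeg_diff["band"] == "gamma"]
            gamma = gamma[gamma["channel"].isin(
                electrodes_of_interest("gamma"))]
            slopes = two_point_slope(gamma, ctab, scale=scale)
            tests = slope_tests_by_session(slopes)
            slopes_report[scale] = {
                "n_slopes": len(slopes),
                "definition": slopes.attrs["definition"],
                "tests": {s: _stat_dict(t) for s, t in tests.items()},
            }
    except Exception as e:  # noqa: BLE001
        raise StageError("stats", str(e)) from e
    report["eeg_anova"] = anova_rows
    report["correlations"] = correlations
    report["two_point_slopes"] = slopes_report

    # -- TTL inference (baseline session excluded: its differential is
    #    deterministically zero) -----------------------------------------
    try:
        ttl_resp = ttl_kept[ttl_kept["session"] > 1].rename(
            columns={"ttl_differential_s": "value_uV"})
        ttl_anova = anova_condition_session(ttl_resp)
        report["ttl_anova"] = {k: _stat_dict(v)
                               for k, v in ttl_anova.items()}
    except Exception as e:  # noqa: BLE001
        raise StageError("stats", str(e)) from e

    # -- thermography -----------------------------------------------------
    try:
        thermo = {}
        for cond in CONDITIONS:
            first = [cohort.thermograms[(p, cond, "first")]
                     for p in retained]
            last = [cohort.thermograms[(p, cond, "last")]
                    for p in retained]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = skin_temperature_change(
                    first, last, mode=config.thermo_ttest_mode)
            thermo[cond] = _stat_dict(res) | {
                k: _jsonify(v) for k, v in res.extra.items()}
    except Exception as e:  # noqa: BLE001
        raise StageError("thermography", str(e)) from e
    report["thermography"] = thermo

    report["log"] = log
    report["counts"] = {"n_input": n0, "n_retained": len(retained),
                        "delta_limit_uV":
                            DELTA_AMPLITUDE_LIMIT_UV[config.season]}
    return report


def gamma_condition_anova(sim_config: SimulationConfig,
                          channel: str = "Pz",
                          include_session1: bool = True):
    """Condition x session ANOVA on gamma differentials for one synthetic
    cohort, at one electrode of interest.

    This is the pipeline's EEG inference path (generate -> re-reference ->
    band table -> differential from the first session -> balanced ANOVA)
    restricted to the gamma band, which keeps repeated power/type-I
    simulations affordable.  Returns the 'condition' StatResult.
    """
    gamma_band = tuple(b for b in DEFAULT_BANDS if b.name == "gamma")
    tables = []
    for pid in sim_config.participants:
        for cond in CONDITIONS:
            rec = rereference(generate_eeg_recording(pid, cond, sim_config))
            tables.append(session_band_table(rec, gamma_band))
    table = pd.concat(tables, ignore_index=True)
    diff = differential_from_first(table)
    sub = diff[diff["channel"] == channel]
    if not include_session1:
        sub = sub[sub["session"] > 1]
    return anova_condition_session(sub)["condition"]


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
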