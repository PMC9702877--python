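"""End-to-end scenario orchestration on synthetic data.

Each scenario reproduces one study arm — serum degradation of genomic
HMW chromatin, ex vivo NET production, NET degradation in serum, the
NE/MPO enzyme-supplementation experiment, a two-group mouse
fragmentome comparison, and the clinical biomarker cohort — running
the generators and analysis modules with a single mandatory seed and
writing machine-readable CSV/JSON outputs plus a provenance sidecar
(package version, config hash, seed). Outputs are deterministic given
(config, seed): re-running a scenario yields byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import fragkin
from fragkin.errors import SpecificationError
from fragkin import kinetics as kin_mod
from fragkin.cohort_stats import compare_groups, correlation_matrix, summarize
from fragkin.fragmentomics import (
    build_profile,
    detect_peaks,
    estimate_periodicity,
    nucleosomal_fractions,
)
from fragkin.kinetics import (
    TimeCourse,
    degradation_rate,
    enzyme_rate,
    fold_decrease,
    nuclease_rate,
    percent_degraded,
)
from fragkin.qpcr import KRAS_ASSAY, SRY_ASSAY, amplifiable_fraction
from fragkin.synthetic.cohort_sim import COHORT_MARKERS, default_cohort_specs, simulate_cohort
from fragkin.synthetic.degradation import (
    default_ghmw_kinetics,
    default_net_kinetics,
    simulate_degradation,
)
from fragkin.synthetic.net_production import STIMULI, simulate_net_production
from fragkin.synthetic.populations import (
    ghmw_population,
    healthy_population,
    net_supernatant_population,
    sample_fragment_lengths,
)

__all__ = ["SCENARIOS", "ScenarioConfig", "run_scenario", "validate_inputs", "PRINTED_GHMW_TABLE"]

SCENARIOS = (
    "ghmw_degradation",
    "net_production",
    "net_degradation",
    "ne_mpo_degradation",
    "mouse_fragmentome",
    "cohort",
)

#: Endpoint concentrations (ng/mL) of the enzyme-supplementation
#: experiment: 500 ng gHMW DNA per mL of fluid, sampled at 2 h and 8 h.
#: Plasma values follow from the ~95% / ~85% remaining under EDTA.
PRINTED_GHMW_TABLE: dict[str, dict[float, float]] = {
    "serum": {0.0: 500.0, 120.0: 207.0, 480.0: 124.0},
    "serum+NE": {0.0: 500.0, 120.0: 64.0, 480.0: 23.0},
    "serum+MPO": {0.0: 500.0, 120.0: 35.0, 480.0: 16.0},
    "serum+NE+MPO": {0.0: 500.0, 480.0: 5.0},
    "plasma_EDTA": {0.0: 500.0, 120.0: 475.0, 480.0: 425.0},
}


@dataclass
class ScenarioConfig:
    """Validated configuration of one pipeline scenario."""

    scenario: str
    seed: int
    out_dir: Path
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise SpecificationError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )
        if not isinstance(self.seed, int):
            raise SpecificationError("seed is mandatory and must be an integer")
        self.out_dir = Path(self.out_dir)
        if not isinstance(self.params, dict):
            raise SpecificationError("params must be a mapping")

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise SpecificationError("scenario config must be a YAML mapping")
        missing = {"scenario", "seed", "out_dir"} - set(raw)
        if missing:
            raise SpecificationError(f"scenario config missing keys: {sorted(missing)}")
        return cls(
            scenario=raw["scenario"],
            seed=raw["seed"],
            out_dir=Path(raw["out_dir"]),
            params=raw.get("params", {}),
        )

    def digest(self) -> str:
        canon = json.dumps(
            {"scenario": self.scenario, "seed": self.seed, "params": self.params},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def _profile_fractions(result, n_fragments: int, rng, source: str) -> pd.DataFrame:
    rows = []
    for t, pop in zip(result.time_course.times, result.populations):
        lengths = sample_fragment_lengths(pop, n_fragments, rng)
        prof = build_profile(lengths, source=source)
        fr = nucleosomal_fractions(prof)
        rows.append({"time_min": t, **{k: fr[k] for k in ("mono", "di", "tri", "long", "residual")}})
    return pd.DataFrame(rows)


def _dii_series(result, assay) -> list[float]:
    out = []
    for pop in result.populations:
        short = amplifiable_fraction(pop, assay.short_len)
        long_ = amplifiable_fraction(pop, assay.long_len)
        out.append(long_ / short if short > 0 else float("nan"))
    return out


def _run_ghmw_degradation(cfg: ScenarioConfig, out: Path) -> dict:
    p = cfg.params
    times = p.get("times", [0, 5, 30, 120, 480, 1440])
    c0 = p.get("c0_ng_per_ml", 400.0)  # 200 ng chromatin in 0.5 mL fluid
    n_frag = p.get("n_fragments", 50_000)
    rng = np.random.default_rng(cfg.seed)
    pop, kin = ghmw_population(), default_ghmw_kinetics()

    tcs, fracs = [], []
    for condition in ("plasma_EDTA", "serum"):
        res = simulate_degradation(pop, c0, kin, condition, times)
        df = res.time_course.to_frame()
        df["dii"] = _dii_series(res, KRAS_ASSAY)
        tcs.append(df)
        fr = _profile_fractions(res, n_frag, rng, source="all")
        fr.insert(0, "condition", condition)
        fracs.append(fr)
        if condition == "serum":
            end_lengths = sample_fragment_lengths(res.populations[-1], n_frag, rng)
            end_profile = build_profile(end_lengths)
            peaks = detect_peaks(end_profile)
            period = estimate_periodicity(end_profile)
    _write_csv(pd.concat(tcs, ignore_index=True), out / "time_course.csv")
    _write_csv(pd.concat(fracs, ignore_index=True), out / "fractions.csv")
    _write_json(
        {
            "endpoint_serum_peaks_bp": peaks.positions()[:5],
            "subnucleosomal_periodicity_bp": period,
        },
        out / "peaks.json",
    )
    return {"files": ["time_course.csv", "fractions.csv", "peaks.json"]}


def _run_net_degradation(cfg: ScenarioConfig, out: Path) -> dict:
    p = cfg.params
    times = p.get("times", [0, 5, 10, 20, 30, 120, 480, 1440])
    # 50 ng NET DNA carried in 200 uL supernatant into 500 uL of fluid
    c0 = p.get("c0_ng_per_ml", 50.0 / 0.7)
    n_frag = p.get("n_fragments", 100_000)
    condition = p.get("condition", "serum")
    rng = np.random.default_rng(cfg.seed)
    pop, kin = net_supernatant_population(), default_net_kinetics()

    res = simulate_degradation(pop, c0, kin, condition, times)
    df = res.time_course.to_frame()
    df["dii"] = _dii_series(res, SRY_ASSAY)
    df["percent_lost"] = [
        percent_degraded(res.time_course.at(0), c) for c in res.time_course.concentrations
    ]
    _write_csv(df, out / "time_course.csv")
    fr = _profile_fractions(res, n_frag, rng, source="chrY")
    fr.insert(0, "condition", condition)
    _write_csv(fr, out / "fractions.csv")
    end_lengths = sample_fragment_lengths(res.populations[-1], n_frag, rng)
    end_profile = build_profile(end_lengths, source="chrY")
    _write_csv(end_profile.to_frame(), out / "endpoint_profile.csv")
    endpoint = fr.iloc[-1]
    _write_json(
        {
            "condition": condition,
            "endpoint_time_min": float(times[-1]),
            "percent_lost_endpoint": float(df["percent_lost"].iloc[-1]),
            "mono_fraction_endpoint_pct": float(endpoint["mono"] * 100.0),
            "di_fraction_endpoint_pct": float(endpoint["di"] * 100.0),
        },
        out / "summary.json",
    )
    return {"files": ["time_course.csv", "fractions.csv", "endpoint_profile.csv", "summary.json"]}


def _run_net_production(cfg: ScenarioConfig, out: Path) -> dict:
    p = cfg.params
    times = p.get("times", [0, 30, 60, 120, 240, 300])
    rng = np.random.default_rng(cfg.seed)
    frames = {s: simulate_net_production(times, s, rng) for s in STIMULI}
    _write_csv(pd.concat(frames.values(), ignore_index=True), out / "production.csv")

    corr, folds = {}, {}
    for s in ("PMA", "LPS"):
        df = frames[s]
        corr[s] = {
            "r_nDNA_NE": float(np.corrcoef(df["cf_nDNA"], df["NE"])[0, 1]),
            "r_nDNA_MPO": float(np.corrcoef(df["cf_nDNA"], df["MPO"])[0, 1]),
            "r_nDNA_mtDNA": float(np.corrcoef(df["cf_nDNA"], df["cf_mtDNA"])[0, 1]),
        }
        folds[s] = {
            m: float(df[m].iloc[-1] / frames["control"][m].iloc[-1])
            for m in ("cf_nDNA", "cf_mtDNA", "NE", "MPO")
        }
    _write_json(corr, out / "correlations.json")
    _write_json(folds, out / "fold_vs_control.json")
    return {"files": ["production.csv", "correlations.json", "fold_vs_control.json"]}


def _courses_from_table(table: dict[str, dict[float, float]]) -> dict[str, TimeCourse]:
    return {
        cond: TimeCourse(
            condition=cond,
            times=sorted(vals),
            concentrations=[vals[t] for t in sorted(vals)],
        )
        for cond, vals in table.items()
    }


def _run_ne_mpo_degradation(cfg: ScenarioConfig, out: Path) -> dict:
    p = cfg.params
    if "concentration_table" in p:
        df = pd.read_csv(p["concentration_table"])
        table: dict[str, dict[float, float]] = {}
        for _, row in df.iterrows():
            table.setdefault(row["condition"], {})[float(row["time_min"])] = float(
                row["conc_ng_per_ml"]
            )
    else:
        table = PRINTED_GHMW_TABLE
    courses = _courses_from_table(table)
    serum = courses["serum"]

    folds = {}
    for cond, tc in courses.items():
        if cond == "serum" or not cond.startswith("serum+"):
            continue
        enzyme = cond.removeprefix("serum+")
        for t in tc.times:
            if t == 0 or t not in serum.times:
                continue
            hours = int(t // 60)
            folds[f"{enzyme}_{hours}h"] = {
                "raw": fold_decrease(serum.at(t), tc.at(t)),
                "reported": fold_decrease(serum.at(t), tc.at(t), rounding="auto"),
                "reported_integer": fold_decrease(serum.at(t), tc.at(t), rounding="integer"),
            }
    _write_json(folds, out / "folds.json")

    rows = []
    for cond, tc in courses.items():
        for t0, t1 in ((0.0, 120.0), (120.0, 480.0), (0.0, 480.0)):
            if t0 in tc.times and t1 in tc.times:
                est = degradation_rate(tc, t0, t1)
                rows.append(
                    {"condition": cond, "t0_min": t0, "t1_min": t1,
                     "rate_ng_per_ml_min": est.rate, "attribution": est.attribution}
                )
    if "plasma_EDTA" in courses:
        for t0, t1 in ((0.0, 120.0), (0.0, 480.0)):
            est = nuclease_rate(serum, courses["plasma_EDTA"], (t0, t1))
            rows.append(
                {"condition": "serum-vs-plasma", "t0_min": t0, "t1_min": t1,
                 "rate_ng_per_ml_min": est.rate, "attribution": est.attribution}
            )
    for cond, tc in courses.items():
        if not cond.startswith("serum+"):
            continue
        for t0, t1 in ((0.0, 120.0), (0.0, 480.0)):
            if t1 in tc.times:
                est = enzyme_rate(tc, serum, (t0, t1), attribution=cond.removeprefix("serum+"))
                rows.append(
                    {"condition": cond, "t0_min": t0, "t1_min": t1,
                     "rate_ng_per_ml_min": est.rate, "attribution": est.attribution}
                )
    _write_csv(pd.DataFrame(rows), out / "rates.csv")

    pct = {
        cond: {f"{int(t)}min": percent_degraded(tc.at(0), tc.at(t)) for t in tc.times if t > 0}
        for cond, tc in courses.items()
    }
    _write_json(pct, out / "percent_degraded.json")
    return {"files": ["folds.json", "rates.csv", "percent_degraded.json"]}


def _run_mouse_fragmentome(cfg: ScenarioConfig, out: Path) -> dict:
    """Wild-type vs nuclease-impaired fragmentome comparison.

    The knockout-like group keeps more oligonucleosomal DNA and less
    sub-nucleosomal ladder, emulating reduced degradation capacity.
    """
    p = cfg.params
    n_frag = p.get("n_fragments", 50_000)
    rng = np.random.default_rng(cfg.seed)
    wt = healthy_population()
    ko = wt.reweighted({"subnuc": 0.01, "monoN": 0.58, "diN": 0.30, "triN": 0.09, "hmw": 0.02})
    profiles, summary = [], {}
    for label, pop in (("WT", wt), ("NE_KO", ko)):
        lengths = sample_fragment_lengths(pop, n_frag, rng)
        prof = build_profile(lengths)
        df = prof.to_frame()
        df.insert(0, "genotype", label)
        profiles.append(df)
        fr = nucleosomal_fractions(prof)
        summary[label] = {
            "mode_bp": detect_peaks(prof).positions()[0],
            "mono_fraction": fr["mono"],
            "di_fraction": fr["di"],
        }
    _write_csv(pd.concat(profiles, ignore_index=True), out / "profiles.csv")
    _write_json(summary, out / "summary.json")
    return {"files": ["profiles.csv", "summary.json"]}


def _run_cohort(cfg: ScenarioConfig, out: Path) -> dict:
    rng = np.random.default_rng(cfg.seed)
    table = simulate_cohort(default_cohort_specs(), rng)
    _write_csv(table, out / "cohort.csv")
    _write_csv(summarize(table), out / "summary.csv")
    comparisons = {}
    for group in ("COVID-19", "SLE", "mCRC"):
        for marker in ("cir_nDNA", "NE", "MPO"):
            c = compare_groups(table, marker, group, "HI")
            comparisons[f"{group}|{marker}"] = {
                "median_group": c.median_a,
                "median_HI": c.median_b,
                "U": c.u_statistic,
                "p": c.p_value,
                "stars": c.stars,
            }
    _write_json(comparisons, out / "comparisons.json")
    correlations = {}
    for group in ("HI", "COVID-19", "SLE", "mCRC"):
        res = correlation_matrix(table, list(COHORT_MARKERS), group=group, log_scale=True)
        correlations[group] = {
            "method": res.method,
            "r": {c: res.r[c].round(4).to_dict() for c in res.r.columns},
        }
    _write_json(correlations, out / "correlations.json")
    return {"files": ["cohort.csv", "summary.csv", "comparisons.json", "correlations.json"]}


_RUNNERS = {
    "ghmw_degradation": _run_ghmw_degradation,
    "net_production": _run_net_production,
    "net_degradation": _run_net_degradation,
    "ne_mpo_degradation": _run_ne_mpo_degradation,
    "mouse_fragmentome": _run_mouse_fragmentome,
    "cohort": _run_cohort,
}


def run_scenario(config: ScenarioConfig) -> dict:
    """Run one scenario; returns the report manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = _RUNNERS[config.scenario](config, out)
    report.update(scenario=config.scenario, seed=config.seed)
    provenance = {
        "package": "fragkin",
        "version": fragkin.__version__,
        "scenario": config.scenario,
        "seed": config.seed,
        "config_hash": config.digest(),
        "params": config.params,
    }
    _write_json(provenance, out / "provenance.json")
    _write_json(report, out / "manifest.json")
    return report


# ---------------------------------------------------------------------------
# input validation


_CSV_SCHEMAS = {
    "cq_table": {"sample", "target", "amplicon", "replicate", "Cq"},
    "time_course": {"condition", "time_min", "conc_ng_per_ml"},
    "cohort_table": {"group", "cir_nDNA", "NE", "MPO"},
    "ce_trace": {"size_bp", "signal"},
}


def _validate_one(path: Path) -> dict:
    report = {"path": str(path), "format": None, "ok": False, "n_records": 0, "problems": []}
    if not path.exists():
        report["problems"].append("file does not exist")
        return report
    suffix = path.suffix.lower()
    try:
        if suffix in (".sam", ".bam"):
            import pysam

            report["format"] = "alignment"
            with pysam.AlignmentFile(str(path), check_sq=False) as fh:
                n = sum(1 for _ in fh)
            report["n_records"] = n
            report["ok"] = True
        elif suffix == ".tsv":
            df = pd.read_csv(path, sep="\t")
            report["format"] = "fragment_tsv"
            report["n_records"] = len(df)
            missing = {"chrom", "length"} - set(df.columns)
            if missing:
                report["problems"].append(f"missing required columns: {sorted(missing)}")
            else:
                report["ok"] = True
        elif suffix == ".csv":
            df = pd.read_csv(path)
            report["n_records"] = len(df)
            cols = set(df.columns)
            for name, required in _CSV_SCHEMAS.items():
                if required <= cols:
                    report["format"] = name
                    report["ok"] = True
                    break
            else:
                report["format"] = "csv"
                best = max(_CSV_SCHEMAS, key=lambda k: len(_CSV_SCHEMAS[k] & cols))
                missing = _CSV_SCHEMAS[best] - cols
                report["problems"].append(
                    f"no known schema matches; closest is {best!r}, missing {sorted(missing)}"
                )
        else:
            report["problems"].append(f"unrecognized extension {suffix!r}")
    except Exception as exc:  # unreadable file: listed, not fatal to the batch
        report["problems"].append(f"unreadable: {exc}")
    return report


def validate_inputs(paths) -> list[dict]:
    """Validate a batch of input files; never mutates them.

    Each file gets a report (detected format, record count, schema
    violations); an unreadable file is reported but does not abort the
    rest of the batch.
    """
    return [_validate_one(Path(p)) for p in paths]
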