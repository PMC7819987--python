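"""End-to-end study orchestration.

``run_study`` reproduces the complete analysis workflow on one cohort:
eligibility filtering, sign ascertainment (read from the table, or
detected on CT volumes in image mode), propensity-score estimation,
greedy caliper matching, covariate balance before/after, the odds-ratio
ladder across adjustment schemes, a sensitivity analysis restricted to
scans with at least three hematomas, predefined subgroup/interaction
analyses on the matched sample, and an ROC comparison of the sign
against simpler predictors on the pre-matched cohort.

``summarize_fixture`` recomputes headline proportions from the published
patient counts packaged with this library.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .cohortsim import CohortParams, generate_cohort, apply_eligibility
from .imaging import (
    SegmentationConfig,
    classify_expansion,
    detect_fuzzy_sign,
    segment_hematomas,
    total_hematoma_volume,
)
from .matchstats import (
    PS_COVARIATES,
    adjusted_or,
    balance_report,
    estimate_propensity,
    greedy_match,
    matched_conditional_or,
    odds_ratio_2x2,
    roc_auc,
    roc_curve_points,
    subgroup_interaction,
)
from .volume import CTVolume

MIN_PAIRS = 10


@dataclass
class StudyConfig:
    """Configuration for one study run."""

    mode: str = "table"  # "table" or "image"
    seed: int = 0
    cohort_params: CohortParams | None = None
    cohort: pd.DataFrame | None = None  # pre-built table (table mode)
    image_table: pd.DataFrame | None = None  # covariates + scan paths
    segmentation: SegmentationConfig | None = None
    covariates: tuple = PS_COVARIATES
    caliper: float = 0.05
    output_dir: str | None = None

    def validate(self) -> None:
        if self.mode not in ("table", "image"):
            raise ValueError("mode must be 'table' or 'image'")
        if self.mode == "image" and self.image_table is None:
            raise ValueError("image mode requires image_table")
        if self.caliper <= 0:
            raise ValueError("caliper must be positive")


@dataclass
class StudyReport:
    """Serializable results of one full study run."""

    eligibility: dict
    baseline_table: list
    effect_table: list
    sensitivity_table: list
    balance: list
    subgroups: list
    roc: dict
    matching: dict
    seed: int

    def as_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "StudyReport":
        return cls(**json.loads(text))

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        pd.DataFrame(self.effect_table).to_csv(
            out / "effect_table.csv", index=False
        )
        pd.DataFrame(self.sensitivity_table).to_csv(
            out / "sensitivity_table.csv", index=False
        )
        pd.DataFrame(self.balance).to_csv(out / "balance.csv", index=False)
        pd.DataFrame(self.subgroups).to_csv(
            out / "subgroups.csv", index=False
        )
        pd.DataFrame(self.baseline_table).to_csv(
            out / "baseline_table.csv", index=False
        )
        for name, entry in self.roc.items():
            pd.DataFrame(entry["curve"]).to_csv(
                out / f"roc_{name}.csv", index=False
            )


# ----------------------------------------------------------- image mode


def sign_and_volumes_from_images(
    table: pd.DataFrame, cfg: SegmentationConfig | None = None
) -> pd.DataFrame:
    """Fill sign / volume / expansion columns by analyzing CT volumes.

    ``table`` needs ``baseline_path`` and optionally ``followup_path``
    columns pointing at NIfTI files.  Baseline volume is the total
    hematoma burden; the sign is detected on the baseline scan; the
    expansion flag applies the growth rule when a follow-up is present.
    """
    cfg = cfg or SegmentationConfig()
    out = table.copy()
    signs, n_hem, base_ml, fu_ml, expanded = [], [], [], [], []
    for _, row in table.iterrows():
        vol = CTVolume.from_nifti(row["baseline_path"])
        comps = segment_hematomas(vol, cfg)
        ev = detect_fuzzy_sign(vol, comps, cfg)
        signs.append(int(ev.sign))
        n_hem.append(len(comps))
        b = total_hematoma_volume(comps)
        base_ml.append(b)
        if "followup_path" in table.columns and isinstance(
            row["followup_path"], str
        ):
            fvol = CTVolume.from_nifti(row["followup_path"])
            f = total_hematoma_volume(segment_hematomas(fvol, cfg))
            fu_ml.append(f)
            expanded.append(int(classify_expansion(b, f).expanded))
        else:
            fu_ml.append(np.nan)
            expanded.append(np.nan)
    out["sign"] = signs
    out["n_hematomas"] = n_hem
    out["baseline_volume_ml"] = base_ml
    out["followup_volume_ml"] = fu_ml
    exp = pd.Series(expanded, index=out.index)
    if exp.notna().all():
        out["expanded"] = exp.astype(int)
    elif "expanded" not in out.columns:
        out["expanded"] = exp  # partially imaged cohorts keep NaN flags
    return out


# ------------------------------------------------------------ the study


def _effect_ladder(cohort, ps, matched, seed) -> list:
    """Crude, sex/age-, confounder- and PS-adjusted, and pair-stratified
    odds ratios for the sign-expansion association."""
    rows = []
    a = int(((cohort.sign == 1) & (cohort.expanded == 1)).sum())
    b = int(((cohort.sign == 1) & (cohort.expanded == 0)).sum())
    c = int(((cohort.sign == 0) & (cohort.expanded == 1)).sum())
    d = int(((cohort.sign == 0) & (cohort.expanded == 0)).sum())
    rows.append({**odds_ratio_2x2(a, b, c, d).as_dict(), "method": "crude"})
    for adj in ("sex_age", "individual_confounders", "ps_covariate"):
        rows.append(
            adjusted_or(cohort, adjustment=adj, propensity=ps).as_dict()
        )
    idx = cohort.set_index("id")
    t = idx.loc[matched.treated_ids(), "expanded"].to_numpy(int)
    cc = idx.loc[matched.control_ids(), "expanded"].to_numpy(int)
    est, mc = matched_conditional_or(t, cc)
    row = est.as_dict()
    row["mcnemar_chi2"] = mc.statistic
    row["mcnemar_p"] = mc.p_value
    row["discordant_10"] = mc.n10
    row["discordant_01"] = mc.n01
    rows.append(row)
    return rows


def _baseline_summary(cohort, balance_df) -> list:
    """Table-1-style group summaries joined with standardized
    differences."""
    from .matchstats import _LOC_DUMMIES  # dummy layout shared with balance

    x = cohort.copy()
    x["gcs_moderate"] = (x["gcs_level"] == "moderate").astype(int)
    x["gcs_severe"] = (x["gcs_level"] == "severe").astype(int)
    for lev in _LOC_DUMMIES:
        x[f"loc_{lev}"] = (x["location"] == lev).astype(int)
    rows = []
    for _, brow in balance_df.iterrows():
        name = brow["covariate"]
        rows.append(
            {
                "covariate": name,
                "mean_sign": float(x.loc[x.sign == 1, name].mean()),
                "mean_nosign": float(x.loc[x.sign == 0, name].mean()),
                "smd_before_pct": float(brow["smd_before_pct"]),
                "smd_after_pct": float(brow["smd_after_pct"]),
            }
        )
    return rows


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the full analysis pipeline; deterministic under the
    config seed.  Aborts with a diagnostic if matching yields fewer than
    10 pairs or covariate columns are missing."""
    config.validate()
    seed = config.seed

    if config.mode == "image":
        cohort = sign_and_volumes_from_images(
            config.image_table, config.segmentation
        )
    elif config.cohort is not None:
        cohort = config.cohort.copy()
    else:
        params = config.cohort_params or CohortParams()
        cohort = generate_cohort(params, seed=seed)

    missing = [
        c
        for c in ("sign", "expanded", "time_to_ct_h", "time_to_followup_h")
        if c not in cohort.columns
    ]
    if missing:
        raise ValueError(f"cohort table lacks required columns: {missing}")
    if "id" not in cohort.columns:
        cohort = cohort.reset_index().rename(columns={"index": "id"})

    cohort, elig_counts = apply_eligibility(cohort)

    ps, ps_fit = estimate_propensity(cohort, config.covariates)
    matched = greedy_match(
        ps,
        cohort["sign"].to_numpy(),
        caliper=config.caliper,
        seed=seed,
        ids=cohort["id"].to_numpy(),
    )
    if matched.n_pairs < MIN_PAIRS:
        raise RuntimeError(
            f"matching produced only {matched.n_pairs} pairs "
            f"(caliper {config.caliper}, "
            f"{int(cohort.sign.sum())} sign-positive of {len(cohort)}); "
            "cannot run matched analyses"
        )

    bal = balance_report(cohort, matched)
    effect = _effect_ladder(cohort, ps, matched, seed)

    # sensitivity: restrict to scans with multiple (>=3) hematomas
    multi = cohort[cohort["n_hematomas"] >= 3].reset_index(drop=True)
    sens_rows: list = []
    if multi["sign"].nunique() == 2 and multi["expanded"].nunique() == 2:
        ps_m, _ = estimate_propensity(multi, config.covariates)
        matched_m = greedy_match(
            ps_m,
            multi["sign"].to_numpy(),
            caliper=config.caliper,
            seed=seed + 1,
            ids=multi["id"].to_numpy(),
        )
        if matched_m.n_pairs >= MIN_PAIRS:
            sens_rows = _effect_ladder(multi, ps_m, matched_m, seed)
        else:
            sens_rows = [
                {
                    "method": "unavailable",
                    "note": f"only {matched_m.n_pairs} matched pairs in "
                    "the multiple-hematoma subset",
                }
            ]

    # subgroup / interaction analysis on the matched sample
    idx = cohort.set_index("id")
    matched_rows = pd.concat(
        [idx.loc[matched.treated_ids()], idx.loc[matched.control_ids()]]
    ).reset_index()
    subgroups = subgroup_interaction(matched_rows)

    # ROC comparison on the pre-matched cohort; time-to-CT is oriented so
    # that earlier scanning (more growth still ahead) scores higher
    roc_inputs = {
        "sign": cohort["sign"].to_numpy(float),
        "multiple_hematomas": (cohort["n_hematomas"] >= 3).to_numpy(float),
        "time_to_ct": -cohort["time_to_ct_h"].to_numpy(float),
        "baseline_volume": cohort["baseline_volume_ml"].to_numpy(float),
    }
    outcome = cohort["expanded"].to_numpy(int)
    roc = {}
    for name, pred in roc_inputs.items():
        r = roc_auc(pred, outcome, label=name)
        roc[name] = {
            "auc": r.auc,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "curve": roc_curve_points(pred, outcome).to_dict("list"),
        }

    report = StudyReport(
        eligibility=elig_counts,
        baseline_table=_baseline_summary(cohort, bal),
        effect_table=effect,
        sensitivity_table=sens_rows,
        balance=bal.to_dict("records"),
        subgroups=subgroups.to_dict("records"),
        roc=roc,
        matching={
            "n_pairs": matched.n_pairs,
            "n_unmatched_treated": len(matched.unmatched_treated),
            "caliper": matched.caliper,
            "ps_model_converged": bool(ps_fit.converged),
            "mean_ps": float(np.mean(ps)),
            "sign_prevalence": float(cohort["sign"].mean()),
            "expansion_incidence": float(cohort["expanded"].mean()),
        },
        seed=seed,
    )
    if config.output_dir:
        report.save(config.output_dir)
    return report


# --------------------------------------------------- printed-count facts


def load_printed_counts() -> dict:
    """The published patient counts shipped with the package."""
    text = (
        resources.files("fuzzyct")
        .joinpath("data/printed_counts.json")
        .read_text()
    )
    return json.loads(text)


def summarize_fixture(fixture: dict | None = None) -> dict:
    """Recompute headline proportions from published patient counts.

    All values are percentages on the 0-100 scale.  Raises ``ValueError``
    for a malformed fixture.
    """
    fx = fixture if fixture is not None else load_printed_counts()
    try:
        dev, val = fx["development"], fx["validation"]
        dev_den = dev["matched_group_denominator_implied"]
        out = {
            "dev_sign_prevalence_pct": 100.0 * dev["n_sign"] / dev["n_total"],
            "dev_expansion_incidence_pct": 100.0
            * dev["n_expansion"]
            / dev["n_total"],
            "dev_matched_expansion_sign_pct": 100.0
            * dev["matched_expansion_sign"]
            / dev_den,
            "dev_matched_expansion_nosign_pct": 100.0
            * dev["matched_expansion_nosign"]
            / dev_den,
            "val_expansion_incidence_pct": 100.0
            * val["n_expansion"]
            / val["n_total"],
            "val_matched_expansion_sign_pct": 100.0
            * val["matched_expansion_sign"]
            / val["matched_pairs"],
            "val_matched_expansion_nosign_pct": 100.0
            * val["matched_expansion_nosign"]
            / val["matched_pairs"],
        }
    except (KeyError, TypeError, ZeroDivisionError) as exc:
        raise ValueError(f"malformed printed-count fixture: {exc}") from exc
    return out
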