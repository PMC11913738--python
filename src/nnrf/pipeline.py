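"""End-to-end study orchestration.

Runs the full analysis in the pre-registered order: obtain epochs
(synthetic cohort or epochs file) → baseline correction and amplitude
rejection → outcome-neutral cluster permutation checks (detectable evoked
activity pre vs post stimulus, per stimulus type) → template projection →
the discrimination test (lance > control) → the equivalence test → the
age-correlation test, which is gated on the discrimination test having
confirmed (p < .05) since without discrimination there is no basis to treat
the magnitude as a measure of noxious-evoked activity.

All randomness flows from seeds named in the run manifest; identical
configurations give byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import ClusterConfig, paired_cluster_test
from .epochs import EpochSet
from .preprocess import RejectionCriteria, baseline_correct, reject_epochs, rejection_report
from .stats import (
    EQUIVALENCE_BOUNDS,
    equivalence_test,
    paired_one_tailed_t,
    partial_pearson_site,
)
from .synthetic import CohortConfig, make_template_waveform, simulate_epochset
from .template import Template, WoodyConfig, derive_template, magnitudes, read_template

__all__ = ["RunConfig", "RunManifest", "subset_for_hypothesis", "run_study"]

# Pre-registered inclusion windows (weeks); boundary operators as printed:
# discrimination/equivalence closed at [31, 43] GA and [34, 43] PMA;
# the age-correlation subset is open below 36.0 GA and closed at 37.0 PMA.
_AGE_RULES = {
    "H1": dict(ga=(31.0, 43.0), pma=(34.0, 43.0), both=True),
    "H2": dict(ga=(31.0, 43.0), pma=(34.0, 43.0), both=False),
    "H3": dict(ga=None, pma=None, both=False),  # special-cased below
}


@dataclass
class RunConfig:
    """Configuration of one study run; exactly one input source."""

    cohort: CohortConfig | None = None
    epochs_path: str | None = None
    metadata_path: str | None = None
    rate: float | None = None  # required with epochs_path
    rejection: RejectionCriteria = field(default_factory=RejectionCriteria)
    template_source: str = "synthetic"  # "synthetic" | "derive" | file path
    woody: WoodyConfig = field(default_factory=WoodyConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    run_h1: bool = True
    run_h2: bool = True
    run_h3: bool = True
    n_boot: int = 10_000
    bootstrap_seed: int = 0
    outcome_neutral_override: bool = False
    outdir: str = "nnrf_run"

    def validate(self) -> None:
        if (self.cohort is None) == (self.epochs_path is None):
            raise ValueError("exactly one input source (cohort or epochs_path)")
        if self.epochs_path is not None and self.rate is None:
            raise ValueError("rate is required with an epochs file")


@dataclass
class RunManifest:
    config: dict
    counts: dict  # per stimulus: {"in": .., "rejected": .., "analysed": ..}
    gates: dict
    outputs: dict  # filename -> sha256
    seeds: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def subset_for_hypothesis(cohort: pd.DataFrame, hypothesis: str) -> pd.DataFrame:
    """Apply the pre-registered inclusion rules to a magnitude/metadata table.

    The discrimination subset (H1) keeps participants aged 31.0–43.0 weeks
    GA and 34.0–43.0 weeks PMA with both stimuli surviving; the equivalence
    subset (H2) uses the same ages but requires only the lance; the
    age-correlation subset (H3) keeps lance trials with GA < 36.0 and
    PMA ≤ 37.0 weeks.  Boundary values follow the printed operators.
    """
    h = hypothesis.upper()
    if h not in _AGE_RULES:
        raise ValueError(f"unknown hypothesis {hypothesis!r}")
    if cohort.empty:
        return cohort.copy()
    for col in ("ga_weeks", "pma_weeks"):
        if col not in cohort or cohort[col].isna().any():
            raise ValueError(f"missing demographic field {col!r}")
    ga = cohort["ga_weeks"]
    pma = cohort["pma_weeks"]
    if h == "H3":
        mask = (ga < 36.0) & (pma <= 37.0) & (cohort["stimulus"] == "lance")
        return cohort[mask].copy()
    mask = (ga >= 31.0) & (ga <= 43.0) & (pma >= 34.0) & (pma <= 43.0)
    sub = cohort[mask]
    if h == "H1":
        have_both = (
            sub.groupby("participant")["stimulus"]
            .agg(lambda s: {"lance", "control_lance"} <= set(s))
        )
        keep = have_both[have_both].index
        return sub[sub["participant"].isin(keep)].copy()
    return sub[sub["stimulus"] == "lance"].copy()


def _first_trial_per_participant(df: pd.DataFrame) -> pd.DataFrame:
    """Earliest surviving trial per (participant, stimulus).

    Order follows the epoch/annotation order; ties fall back to the stable
    sort, i.e. first listed wins.
    """
    return df.groupby(["participant", "stimulus"], sort=False).head(1)


def _write_json(path: Path, obj: dict) -> str:
    text = json.dumps(obj, indent=2, sort_keys=True) + "\n"
    path.write_text(text)
    return hashlib.sha256(text.encode()).hexdigest()


def run_study(config: RunConfig) -> RunManifest:
    """Execute the study end to end; writes per-stage outputs to ``outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    # ---- input ------------------------------------------------------
    if config.cohort is not None:
        epochs, meta = simulate_epochset(config.cohort)
        meta = meta.rename(columns={"participant_id": "participant"})
        rate = config.cohort.rate
    else:
        epochs = EpochSet.read_tsv(config.epochs_path, config.rate)
        rate = config.rate
        meta = pd.read_csv(config.metadata_path, sep="\t").rename(
            columns={"participant_id": "participant"}
        )
        epochs.info = epochs.info.merge(
            meta.drop_duplicates(["participant", "stimulus"]),
            on=["participant", "stimulus"],
            how="left",
        )

    # ---- preprocess: baseline + rejection on the analysis window ----
    analysis = reject_epochs(
        baseline_correct(epochs.crop(-500.0, 1000.0)), config.rejection
    )
    report = rejection_report(analysis)
    report_path = outdir / "rejection_report.tsv"
    report.to_csv(report_path, sep="\t", index=False)
    outputs["rejection_report.tsv"] = hashlib.sha256(
        report_path.read_bytes()
    ).hexdigest()

    counts = {}
    for stim in sorted(analysis.info["stimulus"].unique()):
        m = analysis.info["stimulus"] == stim
        counts[stim] = {
            "in": int(m.sum()),
            "rejected": int((m & analysis.rejected).sum()),
            "analysed": int((m & ~analysis.rejected).sum()),
        }

    # ---- outcome-neutral cluster checks ------------------------------
    # full (-1000, +1000) ms epochs, baseline corrected, rejection flags
    # carried over from the analysis-window assessment
    neutral = baseline_correct(epochs)
    neutral.rejected = analysis.rejected.copy()
    gates: dict = {}
    for stim in counts:
        sel = neutral.select((neutral.info["stimulus"] == stim).to_numpy() & neutral.kept)
        if sel.n_epochs < 2:
            gates[f"outcome_neutral_{stim}"] = "FAIL"
            continue
        pre = sel.crop(-1000.0, 0.0).data
        post = sel.crop(0.0, 1000.0).data
        res = paired_cluster_test(pre, post, config.cluster, rate=rate)
        gates[f"outcome_neutral_{stim}"] = "PASS" if res.significant else "FAIL"
        outputs[f"cluster_{stim}.json"] = _write_json(
            outdir / f"cluster_{stim}.json", res.to_dict()
        )
    neutral_ok = all(
        v == "PASS" for k, v in gates.items() if k.startswith("outcome_neutral")
    )
    gates["outcome_neutral_overridden"] = bool(
        not neutral_ok and config.outcome_neutral_override
    )

    proceed = neutral_ok or config.outcome_neutral_override
    h1_confirmed = False
    if proceed:
        # ---- template + projection ----------------------------------
        if config.template_source == "synthetic":
            template = Template.from_waveform(make_template_waveform(rate))
        elif config.template_source == "derive":
            lance = analysis.select(
                (analysis.info["stimulus"] == "lance").to_numpy()
            )
            template = derive_template(lance, config.woody)
        else:
            template = read_template(config.template_source)

        mag = magnitudes(analysis, template, config.woody)
        demo_cols = [
            c for c in ("participant", "stimulus", "site", "ga_weeks", "pma_weeks")
            if c in analysis.info
        ]
        mag = mag.merge(
            analysis.info[demo_cols].drop_duplicates(["participant", "stimulus"]),
            on=[c for c in ("participant", "stimulus", "site") if c in mag],
            how="left",
        )
        mag = _first_trial_per_participant(mag)
        mag_path = outdir / "magnitudes.tsv"
        mag.to_csv(mag_path, sep="\t", index=False, float_format="%.9g")
        outputs["magnitudes.tsv"] = hashlib.sha256(mag_path.read_bytes()).hexdigest()

        # ---- hypothesis tests ---------------------------------------
        if config.run_h1:
            sub = subset_for_hypothesis(mag, "H1")
            lance = sub[sub["stimulus"] == "lance"]
            ctrl = sub[sub["stimulus"] == "control_lance"]
            res1 = paired_one_tailed_t(
                lance["magnitude"], ctrl["magnitude"],
                pairing=(lance["participant"], ctrl["participant"]),
            )
            h1_confirmed = res1.p_one_sided < 0.05
            outputs["h1.json"] = _write_json(
                outdir / "h1.json",
                {**res1.to_dict(), "confirmed": bool(h1_confirmed)},
            )
        if config.run_h2:
            sub = subset_for_hypothesis(mag, "H2")
            res2 = equivalence_test(
                sub["magnitude"].to_numpy(),
                bounds=EQUIVALENCE_BOUNDS,
                n_boot=config.n_boot,
                seed=config.bootstrap_seed,
            )
            outputs["h2.json"] = _write_json(outdir / "h2.json", res2.to_dict())
        gates["h1_confirmed"] = bool(h1_confirmed)
        run_h3 = config.run_h3 and config.run_h1 and h1_confirmed
        gates["h3_ran"] = bool(run_h3)
        if run_h3:
            sub = subset_for_hypothesis(mag, "H3")
            res3 = partial_pearson_site(
                sub["magnitude"].to_numpy(),
                sub["pma_weeks"].to_numpy(),
                sub["site"].to_numpy(),
                n_boot=config.n_boot,
                seed=config.bootstrap_seed + 1,
            )
            outputs["h3.json"] = _write_json(outdir / "h3.json", res3.to_dict())
    else:
        gates["h1_confirmed"] = False
        gates["h3_ran"] = False

    cfg_dict = dataclasses.asdict(config)
    if cfg_dict.get("cohort") is not None:
        cfg_dict["cohort"]["sites"] = dict(cfg_dict["cohort"]["sites"])
    seeds = {
        "cohort": None if config.cohort is None else config.cohort.seed,
        "cluster": config.cluster.seed,
        "bootstrap": config.bootstrap_seed,
    }
    manifest = RunManifest(cfg_dict, counts, gates, outputs, seeds)
    _write_json(outdir / "manifest.json", manifest.to_dict())
    return manifest
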