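"""Orchestrated analysis: recording -> responses -> asymmetry -> statistics.

Stages mirror the estimation chain: Beer-Lambert conversion (when raw
intensities are supplied), zero-phase band-pass, per-session GLM (with the
design columns pushed through the same filter as the data), lesion-side
channel mirroring, LC/TRAC computation, and the group statistics layer.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .asymmetry import compute_asymmetry_table
from .group_stats import (
    StatsReport,
    art_anova,
    average_levels,
    clinical_correlation,
    daily_slopes,
    pairwise_wilcoxon,
)
from .montage_events import Montage, SubjectMeta, build_schedule, load_montage, mirror_responses
from .optics import ExtinctionTable, concentrations_from_od, optical_density
from .preprocess import FilterSpec, bandpass
from .response_glm import HrfSpec, build_design, fit_glm
from .synthetic_cohort import (
    NoiseSpec,
    ResponseScenario,
    SyntheticRecording,
    build_paper_like_cohort,
    simulate_session,
)

log = logging.getLogger("nirsasym")

CHROMOPHORES = ("HbO", "HbR")


def session_responses(
    recording: SyntheticRecording,
    filter_spec: FilterSpec | None = None,
    hrf: HrfSpec | None = None,
    extinction: ExtinctionTable | None = None,
    filter_design: bool = True,
) -> pd.DataFrame:
    """One session's GLM response amplitudes, tidy per (channel, task, chromophore)."""
    filter_spec = filter_spec or FilterSpec()
    if recording.concentrations is not None:
        conc = recording.concentrations
    elif recording.intensities is not None:
        od = optical_density(recording.intensities, baseline="mean", axis=-1)
        hbo, hbr = concentrations_from_od(od[:, 0, :], od[:, 1, :], extinction)
        conc = np.stack([hbo, hbr], axis=1)
    else:
        raise ValueError("recording holds neither concentrations nor intensities")

    design = build_design(recording.schedule, hrf)
    n = min(conc.shape[2], design.values.shape[0])
    conc = conc[:, :, :n]
    design.values = design.values[:n]
    if filter_design:
        design = design.filtered(filter_spec)

    n_ch = conc.shape[0]
    # stack series as columns: (time, channel x chromophore)
    y = conc.reshape(n_ch * 2, n).T
    filtered = bandpass(y, recording.fs, filter_spec, axis=0)
    names = [f"{ch}|{chrom}" for ch in recording.channels for chrom in CHROMOPHORES]
    tidy = fit_glm(filtered, design, series_names=names)
    tidy[["channel", "chromophore"]] = tidy["series"].str.split("|", expand=True)
    return tidy[["channel", "task", "chromophore", "coefficient", "r2", "resid_sd"]]


def analyze_cohort(
    cohort: list[tuple[SubjectMeta, ResponseScenario]],
    montage: Montage | None = None,
    n_blocks: int = 4,
    protocol: str = "clinical",
    filter_spec: FilterSpec | None = None,
    hrf: HrfSpec | None = None,
    index_kinds: tuple[str, ...] = ("LC", "TRAC"),
    alt_variants: tuple[str, ...] = (),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate and analyze every session of a synthetic cohort.

    Returns ``(responses, asymmetry)``: the mirrored tidy coefficient table
    and the LC/TRAC table, both with subject/session/day columns.
    """
    montage = montage or load_montage("clinical28")
    resp_frames = []
    for meta, scenario in cohort:
        proto = protocol if meta.group == "patient" else "healthy"
        blocks = n_blocks if meta.group == "patient" else 3
        frames = []
        for session_id, day in meta.sessions:
            sched = build_schedule(
                proto,
                n_blocks=blocks,
                seed=int(
                    np.random.default_rng(
                        np.random.SeedSequence([seed, scenario.seed, session_id])
                    ).integers(0, 2**31 - 1)
                ),
                session_id=session_id,
                day_index=day,
            )
            rec = simulate_session(montage, sched, scenario, day_index=day, hrf=hrf)
            tidy = session_responses(rec, filter_spec, hrf)
            tidy = tidy[tidy["task"].str.startswith("mi_")].copy()
            tidy["session"] = session_id
            tidy["day"] = day
            frames.append(tidy)
        subj = pd.concat(frames, ignore_index=True)
        subj = mirror_responses(subj, meta, montage)
        subj["subject"] = meta.subject_id
        resp_frames.append(subj)
    responses = pd.concat(resp_frames, ignore_index=True)
    asym = compute_asymmetry_table(
        responses, montage, index_kinds=index_kinds, alt_variants=alt_variants
    )
    return responses, asym


def _pair_label(montage: Montage) -> dict[str, str]:
    out = {}
    for lch, rch in montage.symmetric_pairs:
        out[lch] = f"{lch}|{rch}"
        out[rch] = f"{lch}|{rch}"
    return out


def cohort_statistics(
    asym: pd.DataFrame,
    montage: Montage,
    metas: list[SubjectMeta] | None = None,
    include_subject_term: bool = True,
    alpha: float = 0.05,
) -> StatsReport:
    """The full statistics layer on a multi-subject asymmetry table.

    ART ANOVA per chromophore: hand x channel-pair for LC, hemisphere x
    channel-pair for TRAC; Wilcoxon per symmetric pair on TRAC
    (left-vs-right channel) with BY adjustment; daily slopes when >= 3
    days are present; Pearson correlations against ARAT metadata when
    patient metadata is supplied.
    """
    by_subject = average_levels(asym, "sessions")
    pair_of = _pair_label(montage)
    anova_rows = []
    pair_rows = []
    for chrom in sorted(by_subject["chromophore"].unique()):
        sub = by_subject[by_subject["chromophore"] == chrom]
        lc_rows = sub[sub["index_kind"].str.startswith("LC_")].copy()
        if len(lc_rows):
            lc_rows["hand"] = lc_rows["index_kind"].str.removeprefix("LC_")
            try:
                an = art_anova(
                    lc_rows, factor_a="hand", factor_b="unit",
                    include_subject_term=include_subject_term,
                    effect_names={"A": "hand", "B": "channel", "AB": "hand:channel"},
                )
                an.insert(0, "analysis", f"{chrom} LC")
                anova_rows.append(an)
            except ValueError as e:
                log.warning("LC ANOVA skipped for %s: %s", chrom, e)
        trac_rows = sub[sub["index_kind"] == "TRAC"].copy()
        if len(trac_rows):
            trac_rows["pair"] = trac_rows["unit"].map(pair_of)
            trac_rows = trac_rows.dropna(subset=["pair"])
            try:
                an = art_anova(
                    trac_rows, factor_a="hemisphere", factor_b="pair",
                    include_subject_term=include_subject_term,
                    effect_names={
                        "A": "hemisphere", "B": "channel", "AB": "hemisphere:channel"
                    },
                )
                an.insert(0, "analysis", f"{chrom} TRAC")
                anova_rows.append(an)
            except ValueError as e:
                log.warning("TRAC ANOVA skipped for %s: %s", chrom, e)
            # per-pair Wilcoxon: lesioned-vs-intact channel TRAC differences
            diffs = {}
            piv = trac_rows.pivot_table(
                index="subject", columns="unit", values="value", aggfunc="mean"
            )
            for lch, rch in montage.symmetric_pairs:
                if lch in piv.columns and rch in piv.columns:
                    d = (piv[lch] - piv[rch]).dropna().to_numpy()
                    if d.size:
                        diffs[f"{lch}|{rch}"] = d
            if diffs:
                pt = pairwise_wilcoxon(diffs)
                pt.insert(0, "analysis", f"{chrom} TRAC")
                pair_rows.append(pt)

    slopes = pd.DataFrame()
    if "day" in asym.columns and asym["day"].nunique() >= 3:
        by_day = average_levels(asym, "sessions_within_day")
        slopes = daily_slopes(by_day, alpha=alpha)

    correlations = pd.DataFrame()
    if metas:
        clin_rows = [
            {
                "subject": m.subject_id,
                "baseline_arat": m.baseline_arat,
                "improvement_pct": m.relative_improvement,
            }
            for m in metas
            if m.group == "patient" and m.baseline_arat is not None
        ]
        if len(clin_rows) >= 3:
            trac_mean = (
                by_subject[by_subject["index_kind"] == "TRAC"]
                .assign(hemi=lambda d: d["hemisphere"])
                .pivot_table(index="subject", columns=["chromophore", "hemi"],
                             values="value", aggfunc="mean")
            )
            trac_mean.columns = [f"TRAC_{c}_{h}" for c, h in trac_mean.columns]
            metrics = trac_mean.reset_index()
            correlations = clinical_correlation(metrics, pd.DataFrame(clin_rows))

    return StatsReport(
        anova=pd.concat(anova_rows, ignore_index=True) if anova_rows else pd.DataFrame(),
        pair_tests=pd.concat(pair_rows, ignore_index=True) if pair_rows else pd.DataFrame(),
        slopes=slopes,
        correlations=correlations,
    )


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    out_dir: str = "nirsasym_out"
    montage: str = "clinical28"
    protocol: str = "clinical"
    n_patients: int = 2
    n_healthy: int = 0
    n_blocks: int = 4
    n_days: int | None = 3
    sessions_per_day: int | None = 1
    seed: int = 0
    filter: FilterSpec = field(default_factory=FilterSpec)
    hrf: HrfSpec = field(default_factory=HrfSpec)
    index_kinds: tuple[str, ...] = ("LC", "TRAC")
    alt_variants: tuple[str, ...] = ()
    include_subject_term: bool = True
    alpha: float = 0.05
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "filter" in kwargs:
            kwargs["filter"] = FilterSpec(**kwargs["filter"])
        if "hrf" in kwargs:
            kwargs["hrf"] = HrfSpec(**kwargs["hrf"])
        if "noise" in kwargs:
            kwargs["noise"] = NoiseSpec(**kwargs["noise"])
        for key in ("index_kinds", "alt_variants"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        unknown = set(kwargs) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "out_dir": self.out_dir,
            "montage": self.montage,
            "protocol": self.protocol,
            "n_patients": self.n_patients,
            "n_healthy": self.n_healthy,
            "n_blocks": self.n_blocks,
            "n_days": self.n_days,
            "sessions_per_day": self.sessions_per_day,
            "seed": self.seed,
            "filter": vars(self.filter).copy(),
            "hrf": vars(self.hrf).copy(),
            "index_kinds": list(self.index_kinds),
            "alt_variants": list(self.alt_variants),
            "include_subject_term": self.include_subject_term,
            "alpha": self.alpha,
            "noise": vars(self.noise).copy(),
        }

    @property
    def config_hash(self) -> str:
        # hash the analysis-relevant settings only, not the output location
        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> Path:
    """Simulate a cohort per ``config`` and run the full analysis.

    Writes ``coefficients.csv``, ``asymmetry.csv``, the stats CSV set, a
    text summary, the resolved config and a JSONL stage log into
    ``config.out_dir``; deterministic given the config (which includes the
    seed).  Returns the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    montage = load_montage(config.montage)
    stages = []

    def stage(name):
        stages.append({"stage": name, "t": time.time()})
        log.info("stage: %s", name)

    try:
        stage("simulate")
        cohort = build_paper_like_cohort(
            config.n_patients, config.n_healthy, seed=config.seed,
            montage=montage, noise=config.noise,
            n_days=config.n_days, sessions_per_day=config.sessions_per_day,
        )
        stage("estimate")
        responses, asym = analyze_cohort(
            cohort, montage, n_blocks=config.n_blocks, protocol=config.protocol,
            filter_spec=config.filter, hrf=config.hrf,
            index_kinds=config.index_kinds, alt_variants=config.alt_variants,
            seed=config.seed,
        )
        stage("stats")
        report = cohort_statistics(
            asym, montage, metas=[m for m, _ in cohort],
            include_subject_term=config.include_subject_term, alpha=config.alpha,
        )
    except Exception as e:  # pragma: no cover - error path
        raise RuntimeError(f"pipeline failed at stage {stages[-1]['stage']!r}: {e}") from e

    stage("write")
    header = f"# config_hash: {config.config_hash}\n"
    for name, frame in (("coefficients.csv", responses), ("asymmetry.csv", asym)):
        with open(out / name, "w") as fh:
            fh.write(header)
            frame.to_csv(fh, index=False)
    report.to_csv_dir(out)
    (out / "summary.txt").write_text(header + report.summary() + "\n")
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    with open(out / "log.jsonl", "w") as fh:
        for s in stages:
            fh.write(json.dumps(s) + "\n")
    return out
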