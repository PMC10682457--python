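"""End-to-end study replica: cohort in, tabular statistics out.

Runs the full analysis chain on a synthetic (or user-supplied) cohort:
preprocessing and motion QC, gBOLD-CSF coupling, stage comparisons and the
ordinal trend, biomarker associations within the early-accumulator stage,
rBOLD-CSF and gBOLD-presence maps with cross-hierarchy contrasts,
functional connectivity before/after global-signal removal with the
slope-comparison test, and propagating-wave detection with the
extreme-third subgroup contrast.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import fc_matrix, nuisance_regress, summarize_fc
from .coupling import gbold_csf_coupling, gbold_presence_map, rbold_csf_map
from .hierarchy import HierarchyMasks, assign_hierarchy, cross_hierarchy_contrast, regional_mean
from .preprocess import BoldSession, bandpass_session, session_qc, trim_volumes
from .stats import (
    SubjectRecord,
    TestResult,
    adjust_covariates,
    compare_slopes,
    fdr_bh,
    fisher_exact_2x2,
    log_transform_ab42,
    ordinal_trend,
    spearman_assoc,
    two_sample_ttest,
)
from .synthetic import Cohort, SimulationConfig, generate_cohort
from .waves import (
    MeanWavePattern,
    average_propagations,
    compare_wave_groups,
    detect_session_propagations,
    pg_bin,
)

logger = logging.getLogger("glymphwave.pipeline")

__all__ = ["PipelineConfig", "StudyResults", "run_pipeline", "subgroup_by_marker_thirds"]


@dataclass
class PipelineConfig:
    """Everything needed to rerun the study replica deterministically."""

    mode: str = "synthetic"  # or "real"
    data_dir: str | None = None  # cohort directory in real mode
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0
    trim_front: int = 5
    trim_back: int = 5
    band_low: float = 0.01
    band_high: float = 0.1
    fd_threshold: float = 0.5  # mm; mean FD strictly above excludes
    reference_lag: float = 3.0
    max_lag: float = 12.0
    wave_threshold: float = 0.3
    min_bins: int = 50
    n_bins: int = 70
    interp_factor: int = 5
    window: float = 12.0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError("mode must be 'synthetic' or 'real'")
        if self.mode == "real" and not self.data_dir:
            raise ValueError("real mode requires data_dir")
        for name in ("fd_threshold", "wave_threshold", "n_bins", "interp_factor", "window"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def content_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        for k, v in payload.get("sim", {}).items():
            if isinstance(v, np.ndarray):
                payload["sim"][k] = v.tolist()
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class StudyResults:
    """JSON-serializable summary of one pipeline run."""

    demographics: dict
    stage_comparisons: dict
    marker_associations: dict
    maps: dict
    connectivity: dict
    waves: dict
    provenance: dict
    exclusions: list

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, TestResult):
        return asdict(obj)
    raise TypeError(f"not serializable: {type(obj)}")


def _round_floats(obj, nd=10):
    if isinstance(obj, float):
        return round(obj, nd)
    if isinstance(obj, dict):
        return {k: _round_floats(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, nd) for v in obj]
    return obj


def subgroup_by_marker_thirds(
    records: Sequence[SubjectRecord], marker: str
) -> tuple[list[SubjectRecord], list[SubjectRecord]]:
    """(top_third, bottom_third) of subjects ranked by a marker.

    Each extreme group holds round(n/3) subjects (so 23 subjects yield 8 per
    group); ties are broken deterministically by subject ID.
    """
    recs = list(records)
    n = len(recs)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    k = int(np.floor(n / 3 + 0.5))
    ranked = sorted(recs, key=lambda r: (getattr(r, marker), r.id))
    return ranked[-k:], ranked[:k]


def _test_dict(res: TestResult, family: str | None = None) -> dict:
    d = {"statistic": res.statistic, "p": res.p, "n": res.n, "method": res.method}
    if res.q is not None:
        d["q"] = res.q
    if family:
        d["family"] = family
    return d


def _preprocess_cohort(cohort: Cohort, config: PipelineConfig):
    sessions: dict[str, BoldSession] = {}
    exclusions: list[dict] = []
    for rec in cohort.records:
        sess = cohort.sessions[rec.id]
        try:
            trimmed = trim_volumes(sess, config.trim_front, config.trim_back)
            qc = session_qc(trimmed, config.fd_threshold,
                            config.trim_front, config.trim_back)
            if not qc.included:
                exclusions.append(
                    {"id": rec.id, "stage": "qc", "reason": f"mean FD {qc.mean_fd:.3f} mm"}
                )
                logger.info("excluded %s: mean FD %.3f", rec.id, qc.mean_fd)
                continue
            filtered = bandpass_session(trimmed, config.band_low, config.band_high)
            rec.measures["mean_fd"] = qc.mean_fd
            sessions[rec.id] = filtered
            logger.info("preprocessed %s (stage %s)", rec.id, rec.stage)
        except Exception as exc:
            raise RuntimeError(f"preprocess failed for subject {rec.id}: {exc}") from exc
    return sessions, exclusions


def run_pipeline(config: PipelineConfig) -> StudyResults:
    """Execute the full replica; deterministic for a fixed (config, seed)."""
    if config.mode == "synthetic":
        cohort = generate_cohort(config.sim, seed=config.seed)
    else:
        from .synthetic import Cohort  # noqa: F401  (readers below)
        cohort = _load_cohort(config)
    sessions, exclusions = _preprocess_cohort(cohort, config)
    records = [r for r in cohort.records if r.id in sessions]
    masks = assign_hierarchy(cohort.parcellation)

    # --- coupling per subject -------------------------------------------------
    for rec in records:
        res = gbold_csf_coupling(sessions[rec.id], config.max_lag, config.reference_lag)
        rec.measures["coupling"] = res.coupling_value
        rec.measures["min_lag"] = res.min_lag
        rec.measures["min_value"] = res.min_value

    demo = _demographics(records)
    stage_cmp = _stage_comparisons(records)
    marker_assoc = _marker_associations(records, stage="S2")
    maps = _map_analyses(cohort, sessions, records, masks, config)
    conn = _connectivity_analyses(cohort, sessions, records, masks, stage="S2")
    wave = _wave_analyses(cohort, sessions, records, masks, config, stage="S2")

    provenance = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "version": __version__,
        "n_subjects_in": len(cohort.records),
        "n_subjects_analyzed": len(records),
    }
    results = StudyResults(
        demographics=demo,
        stage_comparisons=stage_cmp,
        marker_associations=marker_assoc,
        maps=maps,
        connectivity=conn,
        waves=wave,
        provenance=provenance,
        exclusions=exclusions,
    )
    if config.out_dir:
        _write_outputs(results, cohort, records, config)
    return results


def _demographics(records: list[SubjectRecord]) -> dict:
    stages = ("S1", "S2", "S3")
    by_stage = {s: [r for r in records if r.stage == s] for s in stages}
    table = {
        s: {
            "n": len(rs),
            "age_mean": float(np.mean([r.age for r in rs])) if rs else np.nan,
            "age_sd": float(np.std([r.age for r in rs], ddof=1)) if len(rs) > 1 else np.nan,
            "n_male": sum(r.sex == "M" for r in rs),
            "n_female": sum(r.sex == "F" for r in rs),
        }
        for s, rs in by_stage.items()
    }
    pairs = [("S2", "S1"), ("S3", "S1"), ("S3", "S2")]
    age_tests, sex_tests = {}, {}
    for a, b in pairs:
        ra, rb = by_stage[a], by_stage[b]
        if len(ra) >= 2 and len(rb) >= 2:
            age_tests[f"{a}_vs_{b}"] = _test_dict(
                two_sample_ttest([r.age for r in ra], [r.age for r in rb])
            )
            tab = [
                [sum(r.sex == "M" for r in rb), sum(r.sex == "F" for r in rb)],
                [sum(r.sex == "M" for r in ra), sum(r.sex == "F" for r in ra)],
            ]
            sex_tests[f"{a}_vs_{b}"] = _test_dict(fisher_exact_2x2(tab))
    return {"table": table, "age_tests": age_tests, "gender_tests": sex_tests}


def _adjusted(records: list[SubjectRecord], key: str) -> np.ndarray:
    values = np.array([r.measures[key] for r in records])
    ages = np.array([r.age for r in records])
    sexes = [r.sex for r in records]
    return adjust_covariates(values, ages, sexes)


def _stage_comparisons(records: list[SubjectRecord]) -> dict:
    staged = [r for r in records if r.stage in ("S1", "S2", "S3")]
    if len({r.stage for r in staged}) < 2 or len(staged) < 8:
        return {"note": "insufficient subjects for stage comparisons",
                "empty_stages": [s for s in ("S1", "S2", "S3")
                                 if not any(r.stage == s for r in staged)]}
    adj = _adjusted(staged, "coupling")
    labels = [r.stage for r in staged]
    out = {"trend": _test_dict(ordinal_trend(adj, labels))}
    for a, b in (("S1", "S2"), ("S1", "S3"), ("S2", "S3")):
        va = adj[[s == a for s in labels]]
        vb = adj[[s == b for s in labels]]
        res = two_sample_ttest(va, vb)
        out[f"{a}_vs_{b}"] = _test_dict(res)
        out[f"{a}_vs_{b}"]["mean_diff"] = float(va.mean() - vb.mean())
    out["stage_means"] = {
        s: float(adj[[l == s for l in labels]].mean()) for s in ("S1", "S2", "S3")
    }
    return out


MARKERS = ("suvr_baseline", "suvr_change_2y", "ln_ab42", "csf_ttau", "csf_ptau")


def _marker_value(rec: SubjectRecord, marker: str):
    if marker == "ln_ab42":
        return log_transform_ab42(rec.csf_ab42) if rec.csf_ab42 else None
    if marker == "suvr_change_2y":
        return rec.suvr_change_2y
    return getattr(rec, marker)


def _marker_associations(records: list[SubjectRecord], stage: str) -> dict:
    """Coupling-biomarker Spearman tests within one stage, FDR over the family."""
    out = {}
    subset = [r for r in records if r.stage == stage]
    results, names = [], []
    for marker in MARKERS:
        rs = [r for r in subset if _marker_value(r, marker) is not None]
        if len(rs) < 4:
            continue
        adj = _adjusted(rs, "coupling")
        y = np.array([_marker_value(r, marker) for r in rs], dtype=float)
        res = spearman_assoc(adj, y)
        results.append(res)
        names.append(marker)
    qs = fdr_bh([r.p for r in results]) if results else []
    for name, res, q in zip(names, results, qs):
        res.q = float(q)
        out[name] = _test_dict(res, family=f"{stage}_marker_associations")
    return {stage: out}


def _map_analyses(cohort, sessions, records, masks: HierarchyMasks,
                  config: PipelineConfig) -> dict:
    """Presence / rBOLD-CSF maps and their links to 2-year amyloid change (S2)."""
    s2 = [r for r in records if r.stage == "S2"]
    presence_maps, rbold_maps = {}, {}
    for r in s2:
        presence_maps[r.id] = gbold_presence_map(sessions[r.id])
        rbold_maps[r.id] = rbold_csf_map(sessions[r.id], config.max_lag, config.reference_lag)
        r.measures["presence_higher"] = regional_mean(presence_maps[r.id], masks.higher)
        r.measures["rbold_higher"] = regional_mean(rbold_maps[r.id], masks.higher)
        r.measures["rbold_lower"] = regional_mean(rbold_maps[r.id], masks.lower)
        r.measures["presence_contrast"] = cross_hierarchy_contrast(presence_maps[r.id], masks)
    out: dict = {}
    if s2:
        mean_presence = pd.concat(presence_maps.values(), axis=1).mean(axis=1)
        mean_rbold = pd.concat(rbold_maps.values(), axis=1).mean(axis=1)
        out["spatial_presence_vs_rbold"] = _test_dict(
            spearman_assoc(mean_presence.to_numpy(), mean_rbold.to_numpy())
        )
        out["group_mean_presence_map"] = {k: float(v) for k, v in mean_presence.items()}
        out["group_mean_rbold_map"] = {k: float(v) for k, v in mean_rbold.items()}
    followup = [r for r in s2 if r.id in cohort.suvr_change_maps]
    if len(followup) >= 4:
        for r in followup:
            change = cohort.suvr_change_maps[r.id]
            r.measures["suvr_change_higher"] = regional_mean(change, masks.higher)
            r.measures["suvr_change_lower"] = regional_mean(change, masks.lower)
            r.measures["suvr_change_contrast"] = cross_hierarchy_contrast(change, masks)
        adj_rb_h = _adjusted(followup, "rbold_higher")
        adj_rb_l = _adjusted(followup, "rbold_lower")
        adj_pres_h = _adjusted(followup, "presence_higher")
        adj_pres_c = _adjusted(followup, "presence_contrast")
        ch_h = np.array([r.measures["suvr_change_higher"] for r in followup])
        ch_l = np.array([r.measures["suvr_change_lower"] for r in followup])
        ch_c = np.array([r.measures["suvr_change_contrast"] for r in followup])
        out["rbold_vs_change_higher"] = _test_dict(spearman_assoc(adj_rb_h, ch_h))
        out["rbold_vs_change_lower"] = _test_dict(spearman_assoc(adj_rb_l, ch_l))
        out["presence_higher_vs_change_contrast"] = _test_dict(
            spearman_assoc(adj_pres_h, ch_c)
        )
        out["presence_contrast_vs_change_contrast"] = _test_dict(
            spearman_assoc(adj_pres_c, ch_c)
        )
    out["masks"] = {
        "higher": sorted(masks.higher),
        "lower": sorted(masks.lower),
        "unassigned": sorted(masks.unassigned),
    }
    return out


def _connectivity_analyses(cohort, sessions, records, masks, stage: str) -> dict:
    """FC-A-beta-42 associations before/after gBOLD removal, with slope tests."""
    subset = [r for r in records if r.stage == stage]
    labels = ("within_higher", "within_lower", "between")
    for r in subset:
        sess = sessions[r.id]
        nuisances = np.column_stack([sess.csf, sess.motion])
        g = sess.gbold()
        for removed in (False, True):
            resid = nuisance_regress(sess.bold, nuisances, include_gbold=removed, gbold=g)
            fc = fc_matrix(resid, sess.parcel_ids, gbold_removed=removed)
            vals = summarize_fc(fc, masks)
            tag = "after" if removed else "before"
            for lab, v in zip(labels, vals):
                r.measures[f"fc_{lab}_{tag}"] = v
    out: dict = {}
    if len(subset) < 4:
        return out
    ln_ab42 = np.array([log_transform_ab42(r.csf_ab42) for r in subset])
    before_p = []
    for lab in labels:
        adj_before = _adjusted(subset, f"fc_{lab}_before")
        adj_after = _adjusted(subset, f"fc_{lab}_after")
        res_b = spearman_assoc(adj_before, ln_ab42)
        res_a = spearman_assoc(adj_after, ln_ab42)
        slope = compare_slopes(ln_ab42, adj_before, adj_after)
        out[lab] = {
            "before": _test_dict(res_b, family="fc_ab42_before"),
            "after": _test_dict(res_a),
            "slope_comparison": {
                **_test_dict(slope),
                "slope_before": slope.extras["slope_before"],
                "slope_after": slope.extras["slope_after"],
            },
        }
        before_p.append(res_b.p)
    for lab, q in zip(labels, fdr_bh(before_p)):
        out[lab]["before"]["q"] = float(q)
    return out


def _wave_analyses(cohort, sessions, records, masks, config: PipelineConfig,
                   stage: str) -> dict:
    """Propagating-wave detection and the extreme-A-beta-42-third group contrast."""
    subset = [r for r in records if r.stage == stage]
    if not subset:
        return {}
    bins = pg_bin(cohort.parcellation.pg, config.n_bins)
    patterns: dict[str, MeanWavePattern] = {}
    counts = {"bottom_up": 0, "top_down": 0, "none": 0, "invalid": 0}
    per_subject = {}
    for r in subset:
        graph, events = detect_session_propagations(
            sessions[r.id], bins, config.interp_factor,
            config.wave_threshold, config.min_bins,
        )
        by_dir = {
            d: [e for e in events if e.direction == d]
            for d in ("bottom_up", "top_down", "none", "invalid")
        }
        for d, evs in by_dir.items():
            counts[d] += len(evs)
        per_subject[r.id] = {d: len(evs) for d, evs in by_dir.items()}
        pat = average_propagations(by_dir["bottom_up"], graph, config.window)
        if not pat.empty:
            patterns[r.id] = pat
    n_events = sum(counts.values())
    valid = n_events - counts["invalid"]
    out: dict = {
        "event_counts": counts,
        "per_subject_counts": per_subject,
        "fraction_valid": valid / n_events if n_events else np.nan,
        "fraction_bottom_up_of_directional": (
            counts["bottom_up"] / (counts["bottom_up"] + counts["top_down"])
            if counts["bottom_up"] + counts["top_down"]
            else np.nan
        ),
    }
    if len(subset) < 3:
        return out
    top, bottom = subgroup_by_marker_thirds(subset, "csf_ab42")
    top_pat = [patterns[r.id] for r in top if r.id in patterns]
    bot_pat = [patterns[r.id] for r in bottom if r.id in patterns]
    out["subgroup_sizes"] = {"top_third": len(top), "bottom_third": len(bottom)}
    if len(top_pat) >= 2 and len(bot_pat) >= 2:
        t_map, p_map = compare_wave_groups(top_pat, bot_pat)
        sig = (p_map < 0.05) & (t_map > 0)  # top group (high A-beta-42) larger
        n_bins = t_map.shape[0]
        third = n_bins // 3
        out["group_contrast"] = {
            "n_top": len(top_pat),
            "n_bottom": len(bot_pat),
            "frac_sig_high_pg": float(sig[-third:].mean()),
            "frac_sig_low_pg": float(sig[:third].mean()),
            "mean_t_high_pg": float(np.nanmean(t_map[-third:])),
            "mean_t_low_pg": float(np.nanmean(t_map[:third])),
        }
    return out


def _load_cohort(config: PipelineConfig) -> Cohort:
    """Read a cohort directory written by ``synthetic.write_cohort`` (real mode)."""
    from .preprocess import load_session
    from .synthetic import GroundTruth

    root = Path(config.data_dir)
    subjects = pd.read_csv(root / "subjects.csv")
    parc_df = pd.read_csv(root / "parcellation.tsv", sep="\t", index_col="parcel_id")
    from .hierarchy import Parcellation

    parc = Parcellation(
        parcel_ids=[str(i) for i in parc_df.index],
        pg=parc_df["pg"].to_numpy(),
        overlaps=parc_df.drop(columns=["pg"]),
    )
    records, sessions = [], {}
    for _, row in subjects.iterrows():
        sid = str(row["id"])
        rec = SubjectRecord(
            id=sid,
            age=float(row["age"]),
            sex=str(row["sex"]),
            csf_ab42=float(row["csf_ab42"]),
            csf_ttau=float(row.get("csf_ttau", np.nan)),
            csf_ptau=float(row.get("csf_ptau", np.nan)),
            suvr_baseline=float(row["suvr_baseline"]),
            suvr_2y=float(row["suvr_2y"]) if pd.notna(row.get("suvr_2y")) else None,
            stage=str(row["stage"]),
        )
        records.append(rec)
        sdir = root / sid
        sessions[sid] = load_session(
            sdir / "bold.tsv", sdir / "csf.tsv", sdir / "motion.tsv",
            tr=config.sim.tr, meta={"subject_id": sid},
        )
    return Cohort(
        parcellation=parc, records=records, sessions=sessions,
        truth={}, suvr_change_maps={}, config=config.sim,
    )


def _write_outputs(results: StudyResults, cohort, records, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "results.json").write_text(
        json.dumps(_round_floats(json.loads(results.to_json())), indent=1, sort_keys=True)
    )
    rows = []
    for r in records:
        row = {
            "id": r.id, "age": r.age, "sex": r.sex, "stage": r.stage,
            "csf_ab42": r.csf_ab42, "csf_ttau": r.csf_ttau, "csf_ptau": r.csf_ptau,
            "suvr_baseline": r.suvr_baseline, "suvr_2y": r.suvr_2y,
        }
        row.update(r.measures)
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "subject_measures.csv", index=False)
    for key in ("group_mean_presence_map", "group_mean_rbold_map"):
        if key in results.maps:
            pd.Series(results.maps[key], name=key).to_csv(
                out / f"{key}.tsv", sep="\t", index_label="parcel_id"
            )
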