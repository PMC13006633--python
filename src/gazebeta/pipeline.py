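"""End-to-end orchestration: simulate → QC → behavior → EEG → clusters →
reports.

Every stage logs its parameters and counts (stage, key=value pairs) to a
standard logger, and the report bundle is written deterministically: given
the same configuration and seeds, two runs produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal

from . import cluster as cl
from . import eeg as eegmod
from . import gaze as gazemod
from . import io as iomod
from . import stats as statsmod
from . import synth
from .kinematics import Condition, default_params
from .montage import MONTAGE_19, default_adjacency, read_adjacency_csv

logger = logging.getLogger("gazebeta")

#: Analysis window for envelope statistics: the visible trajectory phase,
#: 0–2300 ms after onset (epoch samples 200..2499 at 1 kHz).
ANALYSIS_SLICE = slice(200, 2500)


def _log(stage: str, **kv) -> None:
    logger.info("%s %s", stage, " ".join(f"{k}={v}" for k, v in kv.items()))


def preprocess_epochs(
    epochs: np.ndarray,
    *,
    broadband_hz: Tuple[float, float] = (1.0, 40.0),
    order: int = 4,
    fs: float = eegmod.SAMPLING_RATE_HZ,
) -> np.ndarray:
    """Vectorized broadband filter + CAR over (n_epochs × ch × samples)."""
    sos = eegmod._broadband_sos(broadband_hz[0], broadband_hz[1], order, fs)
    out = signal.sosfiltfilt(sos, epochs, axis=-1).astype(np.float32)
    out -= out.mean(axis=-2, keepdims=True, dtype=np.float32)
    return out


def artifact_flags(
    epochs: np.ndarray,
    *,
    threshold_uv: float = eegmod.ARTIFACT_THRESHOLD_UV,
    criterion: str = "absolute",
) -> np.ndarray:
    """Epoch-level rejection flags over (n_epochs × ch × samples)."""
    if criterion == "absolute":
        return np.abs(epochs).max(axis=(-2, -1)) > threshold_uv
    if criterion == "peak_to_peak":
        return (epochs.max(axis=-1) - epochs.min(axis=-1)).max(axis=-1) > threshold_uv
    raise ValueError(f"unknown artifact criterion: {criterion}")


def participant_mean_envelope(
    epochs: np.ndarray,
    keep: np.ndarray,
    *,
    band: Tuple[float, float] = eegmod.LOWBETA_BAND_HZ,
    order: int = 4,
) -> np.ndarray:
    """Mean log-envelope over kept epochs, restricted to the analysis
    window (channels × 2300)."""
    kept = epochs[keep]
    if kept.shape[0] == 0:
        raise ValueError("no artifact-free epochs for this participant")
    env = eegmod.batch_lowbeta_envelope(kept, band=band, order=order)
    return env.mean(axis=0)[:, ANALYSIS_SLICE]


def analyze_cohort(
    sessions: Sequence[synth.SyntheticSession],
    config: Optional[iomod.PipelineConfig] = None,
) -> Dict:
    """Run the complete analysis on in-memory sessions.

    Returns a results dict with QC accounting, per-participant behavioral
    summaries, scalar and series group statistics, participant-mean
    envelopes, and the cluster analysis (when EEG is present).
    """
    config = config or iomod.PipelineConfig()
    geometry = config.geometry.build()
    anchor = tuple(config.anchor_px)
    if config.trajectory_table:
        params_by_condition = iomod.read_trajectory_csv(config.trajectory_table)
    else:
        params_by_condition = {c: default_params(c) for c in Condition}

    # --- EEG preprocessing + artifact flags ------------------------------
    have_eeg = all(s.eeg_epochs is not None for s in sessions)
    envelopes: Dict[str, np.ndarray] = {}
    flags_by_pid: Dict[str, np.ndarray] = {}
    for s in sessions:
        if not have_eeg:
            flags_by_pid[s.participant_id] = np.zeros(len(s.trials), dtype=bool)
            continue
        pre = preprocess_epochs(
            s.eeg_epochs,
            broadband_hz=config.filters.broadband_hz,
            order=config.filters.order,
        )
        flags = artifact_flags(
            pre,
            threshold_uv=config.qc.artifact_threshold_uv,
            criterion=config.qc.artifact_criterion,
        )
        flags_by_pid[s.participant_id] = flags
        _log(
            "eeg", participant=s.participant_id, epochs=len(flags),
            artifacts=int(flags.sum()),
        )
        envelopes[s.participant_id] = None  # placeholder, filled after QC
        s._preprocessed = pre  # cached for the envelope pass

    # --- gaze QC (stepwise: gaze losses first, then EEG artifacts) -------
    qc_rows = []
    kept_trials: Dict[str, List[gazemod.GazeTrial]] = {}
    eeg_keep: Dict[str, np.ndarray] = {}
    for s in sessions:
        flags = flags_by_pid[s.participant_id]
        reasons = []
        keep_mask = np.zeros(len(s.trials), dtype=bool)
        for i, tr in enumerate(s.trials):
            res = gazemod.qc_trial(tr, bool(flags[i]))
            reasons.append(res.reason)
            keep_mask[i] = res.kept
        n_blink = sum(
            r is gazemod.ExclusionReason.BLINK_OR_DROPOUT for r in reasons
        )
        n_art = sum(r is gazemod.ExclusionReason.EEG_ARTIFACT for r in reasons)
        qc_rows.append(
            {
                "participant": s.participant_id,
                "group": s.group,
                "n_trials": len(s.trials),
                "excluded_blink_or_dropout": n_blink,
                "excluded_eeg_artifact": n_art,
                "excluded_total": n_blink + n_art,
                "kept": int(keep_mask.sum()),
            }
        )
        _log(
            "qc", participant=s.participant_id, kept=int(keep_mask.sum()),
            blink=n_blink, artifact=n_art,
        )
        kept_trials[s.participant_id] = [
            tr for tr, k in zip(s.trials, keep_mask) if k
        ]
        eeg_keep[s.participant_id] = keep_mask

    # --- envelopes over kept trials --------------------------------------
    if have_eeg:
        for s in sessions:
            envelopes[s.participant_id] = participant_mean_envelope(
                s._preprocessed,
                eeg_keep[s.participant_id],
                band=config.filters.lowbeta_hz,
                order=config.filters.order,
            )
            del s._preprocessed

    # --- behavioral aggregates and statistics ----------------------------
    summaries = []
    for s in sessions:
        trials = kept_trials[s.participant_id]
        if not trials:
            raise iomod.DataError(
                f"participant {s.participant_id} has zero kept trials"
            )
        summaries.append(
            gazemod.participant_aggregate(
                trials, params_by_condition, geometry, anchor
            )
        )
    group_a = [m for m in summaries if m.group == synth.GROUP_A]
    group_b = [m for m in summaries if m.group == synth.GROUP_B]

    alpha = config.stats.alpha
    scalar_tests = {}
    for name, attr in (("pe_at_response", "pe_at_response"), ("re", "re")):
        a = np.array([getattr(m, attr) for m in group_a])
        b = np.array([getattr(m, attr) for m in group_b])
        scalar_tests[name] = {
            "result": statsmod.compare_groups(a, b, alpha=alpha),
            "a": a,
            "b": b,
        }
        _log(
            "behavior", measure=name,
            t=round(scalar_tests[name]["result"].t, 4),
            p=round(scalar_tests[name]["result"].p, 4),
        )

    series_tests = {}
    for name, attr in (
        ("pe", "pe_series"), ("x", "x_series"), ("y", "y_series"),
    ):
        sa = np.vstack([getattr(m, attr) for m in group_a])
        sb = np.vstack([getattr(m, attr) for m in group_b])
        series_tests[name] = statsmod.pointwise_series_test(sa, sb, alpha=alpha)

    # --- cluster inference ------------------------------------------------
    analysis = None
    if have_eeg:
        if config.cluster.adjacency_path:
            graph = read_adjacency_csv(config.cluster.adjacency_path)
        else:
            graph = default_adjacency()
        env_a = np.stack(
            [envelopes[m.participant] for m in group_a]
        )
        env_b = np.stack(
            [envelopes[m.participant] for m in group_b]
        )
        analysis = cl.cluster_permutation_test(
            env_a,
            env_b,
            graph,
            n_perm=config.cluster.n_perm,
            seed=config.cluster.seed,
            threshold=config.cluster.threshold,
            min_duration_s=config.cluster.min_duration_s,
            time_offset_s=0.0,
        )
        _log(
            "cluster", n_perm=config.cluster.n_perm,
            clusters=len(analysis.clusters),
            significant=len(analysis.significant(alpha)),
        )

    return {
        "config": config,
        "qc": qc_rows,
        "summaries": summaries,
        "scalar_tests": scalar_tests,
        "series_tests": series_tests,
        "envelopes": envelopes if have_eeg else None,
        "cluster_analysis": analysis,
        "graph": default_adjacency() if not have_eeg else graph,
    }


# ---------------------------------------------------------------------------
# report writing


def _cluster_to_dict(c: cl.Cluster) -> dict:
    return {
        "electrodes": list(c.electrode_names),
        "intervals_s": {
            e: [[round(s, 6), round(t, 6)] for s, t in ivs]
            for e, ivs in sorted(c.extents.items())
        },
        "mass": round(c.mass, 6),
        "direction": c.direction,
        "max_run_s": round(c.max_run_s, 6),
        "p": round(c.p, 6),
    }


def write_reports(results: Dict, out_dir) -> List[Path]:
    """Write the report bundle (TSV/JSON/HDF5/YAML) deterministically."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    config: iomod.PipelineConfig = results["config"]
    alpha = config.stats.alpha

    qc = pd.DataFrame(results["qc"])
    p = out / "qc_summary.tsv"
    qc.to_csv(p, sep="\t", index=False)
    written.append(p)

    rows = []
    for m in results["summaries"]:
        rows.append(
            {
                "participant": m.participant,
                "group": m.group,
                "n_trials": m.n_trials,
                "pe_at_response_deg": round(m.pe_at_response, 6),
                "re_s": round(m.re, 6),
            }
        )
    p = out / "behavior_participants.tsv"
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
    written.append(p)

    rows = []
    for name, entry in results["scalar_tests"].items():
        r: statsmod.TestResult = entry["result"]
        a, b = entry["a"], entry["b"]
        rows.append(
            {
                "measure": name,
                "n_a": a.size,
                "mean_a": round(float(a.mean()), 6),
                "sem_a": round(float(a.std(ddof=1) / np.sqrt(a.size)), 6),
                "n_b": b.size,
                "mean_b": round(float(b.mean()), 6),
                "sem_b": round(float(b.std(ddof=1) / np.sqrt(b.size)), 6),
                "levene_F": round(r.levene_F, 6),
                "levene_p": round(r.levene_p, 6),
                "variant": r.variant.value,
                "t": round(r.t, 6),
                "df": round(r.df, 6),
                "p": round(r.p, 6),
                "cohen_d": round(r.d, 6),
                "mean_diff": round(r.mean_diff, 6),
                "ci_low": round(r.ci_low, 6),
                "ci_high": round(r.ci_high, 6),
            }
        )
    p = out / "behavior_scalar_tests.tsv"
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
    written.append(p)

    for name, st in results["series_tests"].items():
        df = pd.DataFrame(
            {
                "bin": np.arange(gazemod.N_SERIES_BINS),
                "time_s": gazemod.SERIES_TIMES_S,
                "t": np.round(st.t, 6),
                "df": np.round(st.df, 6),
                "p_raw": np.round(st.p_raw, 6),
                "p_fdr": np.round(st.p_fdr, 6),
                "n_a": st.n_a,
                "n_b": st.n_b,
                "significant": st.mask.astype(int),
            }
        )
        p = out / f"behavior_series_{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        written.append(p)

    analysis: Optional[cl.ClusterAnalysis] = results["cluster_analysis"]
    if analysis is not None:
        sig = analysis.significant(alpha)
        payload = {
            "n_perm": analysis.null.n_perm,
            "seed": analysis.null.seed,
            "formation_threshold_p": analysis.threshold,
            "min_duration_s": analysis.min_duration_s,
            "adjacency_fingerprint": analysis.adjacency_fingerprint,
            "clusters": [_cluster_to_dict(c) for c in analysis.clusters],
            "n_significant": len(sig),
        }
        p = out / "clusters.json"
        p.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        written.append(p)

        windows = cl.aggregate_windows(
            sig, results["graph"],
            gap_tolerance_s=config.cluster.gap_tolerance_s,
        )
        wpayload = [
            {
                "start_s": round(w.start_s, 6),
                "end_s": round(w.end_s, 6),
                "electrodes": list(w.electrodes),
                "direction": w.direction,
            }
            for w in windows
        ]
        p = out / "windows.json"
        p.write_text(json.dumps(wpayload, indent=2, sort_keys=True) + "\n")
        written.append(p)

        pids = sorted(results["envelopes"])
        groups = {m.participant: m.group for m in results["summaries"]}
        env = np.stack([results["envelopes"][pid] for pid in pids])
        p = out / "envelopes.h5"
        iomod.write_envelopes_h5(
            pids, [groups[pid] for pid in pids], env, p,
        )
        written.append(p)

    p = out / "config_resolved.yaml"
    iomod.dump_config(config, p)
    written.append(p)
    return written


def run_pipeline(
    config: iomod.PipelineConfig,
    sessions: Optional[Sequence[synth.SyntheticSession]] = None,
) -> Dict:
    """Simulate (unless sessions are given), analyze, and write reports.

    Returns the results dict; the report bundle lands in
    ``config.output_dir``.
    """
    if sessions is None:
        sessions = simulate_sessions(config)
    results = analyze_cohort(sessions, config)
    results["reports"] = write_reports(results, config.output_dir)
    return results


def simulate_sessions(config: iomod.PipelineConfig):
    """Build the synthetic cohort described by the config's simulate block."""
    sim = config.simulate
    eeg_cfg = None
    if sim.include_eeg:
        effects = (
            synth.default_beta_effects(sim.beta_gain_uv)
            if sim.beta_gain_uv is not None
            else synth.default_beta_effects()
        )
        eeg_cfg = synth.EEGGenConfig(beta_effects=effects)
    cohort = synth.CohortConfig(
        n_group_a=sim.n_group_a,
        n_group_b=sim.n_group_b,
        trials_per_participant=sim.trials_per_participant,
        seed=sim.seed,
        eeg_config=eeg_cfg,
        include_eeg=sim.include_eeg,
        geometry=config.geometry.build(),
        anchor_px=tuple(config.anchor_px),
    )
    _log(
        "simulate", n_a=sim.n_group_a, n_b=sim.n_group_b,
        trials=sim.trials_per_participant, seed=sim.seed,
        eeg=sim.include_eeg,
    )
    return synth.generate_cohort(cohort)
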