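"""TSV/JSON readers and writers for every pipeline artifact.

The interchange format is tab-delimited UTF-8 with a header row.
Recordings are stored samples x channels with channel labels in the header;
connectivity matrices are stored n x n with labels in header and first
column plus a JSON sidecar carrying band/condition/estimator provenance.
EDF recordings are read through mne when available.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from apnet.behavior import PitchTrial, SubjectScores
from apnet.graph_metrics import AdjacencyMatrix, NetworkMetrics
from apnet.spectral_connectivity import ConnectivityMatrix, EEGRecording
from apnet.synthgen import Cohort

__all__ = [
    "write_recording_tsv",
    "read_recording_tsv",
    "read_recording_edf",
    "write_connectivity_tsv",
    "read_connectivity_tsv",
    "write_edge_list_tsv",
    "write_metrics_tsv",
    "read_metrics_tsv",
    "write_trials_tsv",
    "read_trials_tsv",
    "write_aq_tsv",
    "read_aq_tsv",
    "write_scores_tsv",
    "read_scores_tsv",
    "write_cohort",
]


def write_recording_tsv(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording as samples x channels TSV with a label header."""
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=list(rec.channel_labels))
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            dict(subject_id=rec.subject_id, condition=rec.condition, fs=rec.fs),
            indent=1,
        )
    )
    return path


def read_recording_tsv(
    path: str | Path,
    fs: float | None = None,
    subject_id: str = "",
    condition: str = "",
) -> EEGRecording:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    fs = fs if fs is not None else meta.get("fs")
    if fs is None:
        raise ValueError(f"sampling rate unknown for {path}; pass fs=")
    return EEGRecording(
        subject_id=subject_id or meta.get("subject_id", path.stem),
        condition=condition or meta.get("condition", ""),
        fs=float(fs),
        channel_labels=tuple(df.columns),
        data=df.to_numpy(float).T,
    )


def read_recording_edf(
    path: str | Path, subject_id: str = "", condition: str = ""
) -> EEGRecording:
    """Read an EDF recording via mne (optional dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires mne") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return EEGRecording(
        subject_id=subject_id or Path(path).stem,
        condition=condition,
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        data=raw.get_data(),
    )


def write_connectivity_tsv(conn: ConnectivityMatrix, path: str | Path) -> Path:
    path = Path(path)
    labels = list(conn.channel_labels)
    df = pd.DataFrame(conn.values, index=labels, columns=labels)
    df.to_csv(path, sep="\t", float_format="%.8g")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            dict(
                subject_id=conn.subject_id,
                condition=conn.condition,
                band=conn.band,
                estimator=conn.estimator,
                n_observations=conn.n_observations,
            ),
            indent=1,
        )
    )
    return path


def read_connectivity_tsv(path: str | Path) -> ConnectivityMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return ConnectivityMatrix(
        values=df.to_numpy(float),
        channel_labels=tuple(df.columns),
        subject_id=meta.get("subject_id", ""),
        condition=meta.get("condition", ""),
        band=meta.get("band", ""),
        estimator=meta.get("estimator", "wpli"),
        n_observations=int(meta.get("n_observations", 0)),
    )


def write_edge_list_tsv(adj: AdjacencyMatrix, path: str | Path) -> Path:
    """Write a binary network as a two-column edge list (node_a, node_b)."""
    labels = adj.channel_labels
    rows = [dict(node_a=labels[i], node_b=labels[j]) for i, j in adj.edges()]
    pd.DataFrame(rows, columns=["node_a", "node_b"]).to_csv(
        path, sep="\t", index=False
    )
    return Path(path)


_METRIC_COLS = [
    "subject_id", "group", "condition", "band", "density",
    "C", "L", "C_rand", "L_rand", "gamma", "lambda", "sigma",
]


def write_metrics_tsv(
    rows: Sequence[tuple[str, NetworkMetrics]] | pd.DataFrame,
    path: str | Path,
) -> Path:
    """Write metric rows; ``rows`` is (group, NetworkMetrics) pairs or a frame."""
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame(
            [
                dict(
                    subject_id=m.subject_id, group=group, condition=m.condition,
                    band=m.band, density=m.density, C=m.C_real, L=m.L_real,
                    C_rand=m.C_rand, L_rand=m.L_rand, gamma=m.gamma,
                    **{"lambda": m.lambda_}, sigma=m.sigma,
                )
                for group, m in rows
            ],
            columns=_METRIC_COLS,
        )
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")
    return Path(path)


def read_metrics_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_trials_tsv(
    trials: dict[str, Sequence[PitchTrial]], path: str | Path
) -> Path:
    rows = [
        dict(
            subject_id=sid, block=t.block,
            target=t.target_pitch_class, final_freq_hz=t.final_freq,
        )
        for sid, ts in trials.items()
        for t in ts
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")
    return Path(path)


def read_trials_tsv(path: str | Path) -> dict[str, list[PitchTrial]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[PitchTrial]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["subject_id"]), []).append(
            PitchTrial(
                target_pitch_class=str(row["target"]),
                final_freq=float(row["final_freq_hz"]),
                block=int(row["block"]),
            )
        )
    return out


def write_aq_tsv(responses: dict[str, dict[int, int]], path: str | Path) -> Path:
    rows = [
        dict(subject_id=sid, item=item, response=resp)
        for sid, items in responses.items()
        for item, resp in sorted(items.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return Path(path)


def read_aq_tsv(path: str | Path) -> dict[str, dict[int, int]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[int, int]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["subject_id"]), {})[int(row["item"])] = int(
            row["response"]
        )
    return out


def write_scores_tsv(scores: Sequence[SubjectScores], path: str | Path) -> Path:
    rows = []
    for s in scores:
        row = dict(
            subject_id=s.subject_id, group=s.group, mad=s.mad, sdfom=s.sdfom,
            z_mad=s.z_mad, z_sdfom=s.z_sdfom, aq_total=s.aq_total,
            pis_correct=s.pis_correct, starting_age=s.starting_age,
        )
        row.update({f"aq_{k}": v for k, v in s.aq_subscales.items()})
        row.update(s.covariates)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
    return Path(path)


def read_scores_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write a cohort: recordings, behavioral tables, ground-truth sidecar."""
    out = Path(out_dir)
    rec_dir = out / "recordings"
    rec_dir.mkdir(parents=True, exist_ok=True)
    for subj in cohort.subjects:
        for cond, rec in subj.recordings.items():
            write_recording_tsv(rec, rec_dir / f"{subj.subject_id}_{cond}.tsv")
    write_trials_tsv(
        {s.subject_id: s.pitch_trials for s in cohort.subjects}, out / "trials.tsv"
    )
    write_aq_tsv(
        {s.subject_id: s.aq_responses for s in cohort.subjects}, out / "aq.tsv"
    )
    pis_rows = [
        dict(subject_id=s.subject_id, position=i + 1, answer=a, key=k)
        for s in cohort.subjects
        for i, (a, k) in enumerate(zip(s.pis_answers, cohort.pis_key))
    ]
    pd.DataFrame(pis_rows).to_csv(out / "pis.tsv", sep="\t", index=False)
    cfg = cohort.config
    truth = dict(
        seed=cfg.seed,
        fs=cfg.fs,
        duration_s=cfg.duration_s,
        montage=list(cfg.montage),
        conditions=list(cfg.conditions),
        n_per_group=dict(cfg.n_per_group),
        noise_exponent=cfg.noise_exponent,
        couplings={
            g: [dataclasses.asdict(c) for c in specs]
            for g, specs in cfg.couplings_per_group.items()
        },
        behavior_params={
            g: dataclasses.asdict(p) for g, p in cfg.behavior_params.items()
        },
        subjects=[
            dict(subject_id=s.subject_id, group=s.group, starting_age=s.starting_age)
            for s in cohort.subjects
        ],
    )
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return out
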