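"""Delimited-text persistence for recordings, cohorts, and feature tables.

A recording is stored as a TSV matrix (one column per channel, one row
per sample, header = channel names) with a sidecar event table
(onset_sample, type, session). A cohort directory holds one
recording/event pair per subject-session plus a manifest mapping
subject -> label -> files and a ground-truth table.
"""

from __future__ import annotations

import pathlib
from typing import Dict

import numpy as np
import pandas as pd

from .synth import Cohort, ParadigmSpec, Recording


def write_recording(rec: Recording, data_path, events_path) -> None:
    df = pd.DataFrame(rec.data.T, columns=rec.channel_names)
    df.to_csv(data_path, sep="\t", index=False, float_format="%.6f")
    rec.events.to_csv(events_path, sep="\t", index=False)


def read_recording(data_path, events_path, fs: float,
                   subject: str = "", session: int = 0) -> Recording:
    df = pd.read_csv(data_path, sep="\t")
    events = pd.read_csv(events_path, sep="\t")
    return Recording(data=df.to_numpy(dtype=float).T, fs=fs,
                     channel_names=list(df.columns), events=events,
                     subject=subject, session=session)


def write_cohort(cohort: Cohort, out_dir) -> pathlib.Path:
    """Write all recordings, the manifest, and the ground-truth table."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort.recordings:
        stem = f"{rec.subject}_s{rec.session}"
        data_f, events_f = f"{stem}_data.tsv", f"{stem}_events.tsv"
        write_recording(rec, out / data_f, out / events_f)
        rows.append({"subject": rec.subject, "session": rec.session,
                     "label": cohort.labels[rec.subject],
                     "data_file": data_f, "events_file": events_f,
                     "fs": rec.fs})
    manifest = out / "cohort.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    cohort.ground_truth.to_csv(out / "ground_truth.tsv", sep="\t",
                               index=False)
    return manifest


def read_cohort(manifest_path,
                paradigm: ParadigmSpec = ParadigmSpec()) -> Cohort:
    manifest_path = pathlib.Path(manifest_path)
    base = manifest_path.parent
    manifest = pd.read_csv(manifest_path, sep="\t")
    recordings, labels = [], {}
    for _, row in manifest.iterrows():
        rec = read_recording(base / row["data_file"],
                             base / row["events_file"], fs=row["fs"],
                             subject=row["subject"],
                             session=int(row["session"]))
        recordings.append(rec)
        labels[row["subject"]] = row["label"]
    gt_path = base / "ground_truth.tsv"
    gt = pd.read_csv(gt_path, sep="\t") if gt_path.exists() else pd.DataFrame()
    return Cohort(recordings=recordings, labels=labels, ground_truth=gt,
                  paradigm=paradigm, seed=-1)


def write_feature_tables(tables: Dict[str, pd.DataFrame], out_dir) -> None:
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"features_{name}.tsv", sep="\t", index=False)


def read_feature_tables(in_dir) -> Dict[str, pd.DataFrame]:
    out = {}
    for p in sorted(pathlib.Path(in_dir).glob("features_*.tsv")):
        out[p.stem.removeprefix("features_")] = pd.read_csv(p, sep="\t")
    if not out:
        raise FileNotFoundError(f"no features_*.tsv files in {in_dir}")
    return out


def export_unmixing(result, out_dir, stem: str = "ica") -> None:
    """Optional inspection export of W, A, and source time courses."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / f"{stem}_W.tsv", result.W_full, delimiter="\t")
    np.savetxt(out / f"{stem}_A.tsv", result.A, delimiter="\t")
    np.savetxt(out / f"{stem}_sources.tsv", result.sources.T,
               delimiter="\t", fmt="%.6f")


def export_imfset(imfset, out_dir, stem: str = "oemd") -> None:
    """Optional inspection export of IMFs and the beta matrix."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if imfset.M:
        np.savetxt(out / f"{stem}_imfs.tsv", np.column_stack(imfset.imfs),
                   delimiter="\t", fmt="%.8g")
        np.savetxt(out / f"{stem}_betas.tsv", imfset.betas, delimiter="\t")
    np.savetxt(out / f"{stem}_residue.tsv", imfset.residue, delimiter="\t")
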