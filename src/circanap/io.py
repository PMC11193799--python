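"""Readers and writers for the package's on-disk formats.

Hypnograms are TSV (epoch_index, stage); melatonin series and schedules
are CSV; phase estimates and run manifests are JSON; quantitative maps
and tissue probabilities are NIfTI-1 volumes; protocol configuration is
YAML mirroring :class:`~circanap.protocol.ProtocolConfig` field names.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .melatonin import MelatoninSeries, PhaseEstimate, SBCFParams
from .protocol import ProtocolConfig, ProtocolSchedule, Window
from .simulate import CohortBundle, Hypnogram, QuantMapSet

__all__ = [
    "read_config", "write_config",
    "read_hypnogram", "write_hypnogram",
    "read_melatonin", "write_melatonin",
    "read_schedule", "write_schedule",
    "write_phase", "read_phase",
    "write_quantmaps", "read_quantmaps",
    "write_cohort",
]


def read_config(path) -> ProtocolConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return ProtocolConfig(**data)


def write_config(config: ProtocolConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


def write_hypnogram(hyp: Hypnogram, path) -> None:
    pd.DataFrame(
        {"epoch_index": np.arange(hyp.n_epochs), "stage": hyp.stages}
    ).to_csv(path, sep="\t", index=False)


def read_hypnogram(path, epoch_length: float = 30.0,
                   window_ref: str = "") -> Hypnogram:
    df = pd.read_csv(path, sep="\t")
    ref = window_ref or Path(path).stem
    return Hypnogram(df["stage"].to_numpy(dtype=str), epoch_length, ref)


def write_melatonin(series: MelatoninSeries, path) -> None:
    pd.DataFrame(
        {"minutes_since_wake": series.times_min, "pg_per_ml": series.conc}
    ).to_csv(path, index=False)


def read_melatonin(path) -> MelatoninSeries:
    df = pd.read_csv(path)
    return MelatoninSeries(df["minutes_since_wake"].to_numpy(float),
                           df["pg_per_ml"].to_numpy(float))


def write_schedule(schedule: ProtocolSchedule, path) -> None:
    pd.DataFrame(
        [dict(start_min=w.start, end_min=w.end, kind=w.kind, label=w.label)
         for w in schedule]
    ).to_csv(path, index=False)


def read_schedule(path) -> ProtocolSchedule:
    df = pd.read_csv(path)
    return ProtocolSchedule(tuple(
        Window(r.start_min, r.end_min, r.kind, r.label)
        for r in df.itertuples()
    ))


def write_phase(phase: PhaseEstimate, path) -> None:
    payload = dict(
        dlmon=phase.dlmon, dlmoff=phase.dlmoff, rss=phase.rss,
        converged=phase.converged, fit=dataclasses.asdict(phase.fit),
    )
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_phase(path) -> PhaseEstimate:
    with open(path) as fh:
        d = json.load(fh)
    return PhaseEstimate(d["dlmon"], d["dlmoff"], SBCFParams(**d["fit"]),
                         d["rss"], d["converged"])


def _affine(voxel_size: float) -> np.ndarray:
    aff = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    return aff


def write_quantmaps(maps: QuantMapSet, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aff = _affine(maps.voxel_size)
    for label, vol in maps.maps.items():
        nib.save(nib.Nifti1Image(vol.astype(np.float32), aff),
                 directory / f"{label}.nii")
    nib.save(nib.Nifti1Image(maps.gm_prob.astype(np.float32), aff),
             directory / "gm_prob.nii")
    nib.save(nib.Nifti1Image(maps.wm_prob.astype(np.float32), aff),
             directory / "wm_prob.nii")


def read_quantmaps(directory) -> QuantMapSet:
    directory = Path(directory)
    vols = {}
    for label in ("MTsat", "R1", "R2star"):
        img = nib.load(directory / f"{label}.nii")
        vols[label] = np.asarray(img.dataobj, dtype=float)
    gm_img = nib.load(directory / "gm_prob.nii")
    gm = np.asarray(gm_img.dataobj, dtype=float)
    wm = np.asarray(nib.load(directory / "wm_prob.nii").dataobj, dtype=float)
    voxel_size = float(gm_img.header.get_zooms()[0])
    return QuantMapSet(vols, gm, wm, voxel_size)


def write_cohort(bundle: CohortBundle, directory) -> None:
    """Write a simulated cohort as the per-subject directory layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_schedule(bundle.schedule, directory / "schedule.csv")
    write_config(bundle.config, directory / "protocol.yaml")
    bundle.truth_table().to_csv(directory / "truth.csv")
    cov = bundle.truth_table()[["age", "sex", "education", "napper"]]
    cov.to_csv(directory / "covariates.csv")
    for rec in bundle.subjects:
        sub_dir = directory / rec.subject_id
        (sub_dir / "hypnograms").mkdir(parents=True, exist_ok=True)
        for label, hyp in rec.hypnograms.items():
            write_hypnogram(hyp, sub_dir / "hypnograms" / f"{label}.tsv")
        write_melatonin(rec.melatonin, sub_dir / "melatonin.csv")
        write_quantmaps(rec.maps, sub_dir / "maps")
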