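"""Cohort persistence (HDF5) and delimited-text exports."""

from __future__ import annotations

from io import StringIO
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synthetic import SyntheticCohort
from .types import ACC_AXES, LOCATIONS, SensorStream, gyr_axes_for


def save_cohort(cohort: SyntheticCohort, path: str | Path) -> None:
    """Write a synthetic cohort to one HDF5 file.

    Layout: ``/recordings/<horse>/<trial>/<gait>/<location>/{acc,gyr}``,
    per-horse metadata under ``/horses`` and the ground-truth stride table
    as a CSV-encoded dataset (prescribed per-gait parameters are not
    persisted; the ground truth carries their per-stride values).
    """
    with h5py.File(path, "w") as f:
        f.attrs["seed"] = cohort.seed
        f.attrs["rate"] = cohort.rate
        f.attrs["gaits"] = ",".join(cohort.gaits)
        f.attrs["effect_features"] = ",".join(cohort.effect_features)
        grp = f.create_group("horses")
        str_dt = h5py.string_dtype()
        grp.create_dataset("id", data=np.asarray(cohort.horses, dtype=object), dtype=str_dt)
        grp.create_dataset("max_lactate",
                           data=[cohort.max_lactate[h] for h in cohort.horses])
        grp.create_dataset("intensity_group", dtype=str_dt,
                           data=np.asarray([cohort.intensity_group[h] for h in cohort.horses],
                                           dtype=object))
        rec = f.create_group("recordings")
        for (horse, trial, gait), streams in cohort.recordings.items():
            g = rec.require_group(f"{horse}/{trial}/{gait}")
            for loc, s in streams.items():
                sg = g.create_group(loc)
                sg.create_dataset("acc", data=s.acc, compression="gzip")
                sg.create_dataset("gyr", data=s.gyr, compression="gzip")
        buf = StringIO()
        cohort.ground_truth.to_csv(buf, index=False)
        f.create_dataset("ground_truth_csv", data=buf.getvalue(), dtype=str_dt)


def load_cohort(path: str | Path) -> SyntheticCohort:
    """Read a cohort written by :func:`save_cohort`."""
    with h5py.File(path, "r") as f:
        rate = float(f.attrs["rate"])
        horses = [h.decode() if isinstance(h, bytes) else h for h in f["horses/id"][:]]
        la = {h: float(v) for h, v in zip(horses, f["horses/max_lactate"][:])}
        groups = [g.decode() if isinstance(g, bytes) else g
                  for g in f["horses/intensity_group"][:]]
        intensity = dict(zip(horses, groups))
        recordings = {}
        rec = f["recordings"]
        for horse in rec:
            for trial in rec[horse]:
                for gait in rec[horse][trial]:
                    g = rec[horse][trial][gait]
                    recordings[(horse, trial, gait)] = {
                        loc: SensorStream(location=loc, rate=rate,
                                          acc=g[loc]["acc"][:], gyr=g[loc]["gyr"][:])
                        for loc in g
                    }
        gt_raw = f["ground_truth_csv"][()]
        gt = pd.read_csv(StringIO(gt_raw.decode() if isinstance(gt_raw, bytes) else gt_raw))
        effect_features = [s for s in str(f.attrs["effect_features"]).split(",") if s]
        gaits = tuple(str(f.attrs["gaits"]).split(","))
        seed = int(f.attrs["seed"])
    return SyntheticCohort(
        horses=horses, params={}, recordings=recordings, ground_truth=gt,
        effect_features=effect_features, max_lactate=la, intensity_group=intensity,
        seed=seed, rate=rate, gaits=gaits,
    )


def export_recording_csv(streams: dict, out_dir: str | Path, prefix: str = "") -> list:
    """Write one delimited table per sensor location: time_s, acc_{x,y,z}
    in g and gyr_{x,y,z} in deg/s (axis meanings per location convention)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for loc in LOCATIONS:
        if loc not in streams:
            continue
        s = streams[loc]
        t = np.arange(s.n_samples) / s.rate
        cols = {"time_s": t}
        for i, ax in enumerate(ACC_AXES):
            cols[f"acc_{ax}_g"] = s.acc[i]
        for i, ax in enumerate(gyr_axes_for(loc)):
            cols[f"gyr_{ax}_dps"] = s.gyr[i]
        p = out / f"{prefix}{loc}.csv"
        pd.DataFrame(cols).to_csv(p, index=False)
        paths.append(p)
    return paths
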