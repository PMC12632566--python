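"""Persistence of synthetic sessions.

Layout written by :func:`write_session` into a directory:

* ``signals.h5``      — LFP (channels x samples) and kinematics, with ``fs``
  attributes (HDF5).
* ``events.tsv``      — tab-separated event table (onset_s, offset_s, label,
  tier, fluency and the other annotation columns).
* ``annotations.TextGrid`` — Praat full TextGrid with one interval tier per
  event tier.
* ``electrodes.tsv``  — BIDS-style electrode table (name, x, y, z, region,
  responsive), coordinates in mm.
* ``config.json`` / ``ground_truth.json`` — generator parameters and truth.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import EventTable, Recording, TractKinematics
from .synthgen import SessionConfig, SyntheticSession

__all__ = ["write_session", "read_session", "write_textgrid"]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_textgrid(events: EventTable, path, duration_s: float):
    """Write event tiers as a Praat full ("long") TextGrid."""
    tiers = [t for t in ("utterance", "syllable", "phoneme")
             if (events.df["tier"] == t).any()]
    lines = [
        'File type = "ooTextFile"', 'Object class = "TextGrid"', "",
        "xmin = 0", f"xmax = {duration_s}", "tiers? <exists>",
        f"size = {len(tiers)}", "item []:",
    ]
    for ti, tier in enumerate(tiers, start=1):
        rows = events.tier(tier)
        lines += [f"    item [{ti}]:", '        class = "IntervalTier"',
                  f'        name = "{tier}"', "        xmin = 0",
                  f"        xmax = {duration_s}",
                  f"        intervals: size = {len(rows)}"]
        for k, row in enumerate(rows.itertuples(), start=1):
            lines += [f"        intervals [{k}]:",
                      f"            xmin = {row.onset_s}",
                      f"            xmax = {row.offset_s}",
                      f'            text = "{row.label}"']
    Path(path).write_text("\n".join(lines) + "\n")


def write_session(session: SyntheticSession, directory) -> dict:
    """Persist a session; returns the mapping of artifact name -> path."""
    d = Path(directory)
    try:
        d.mkdir(parents=True, exist_ok=True)
        probe = d / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as err:
        raise OSError(f"directory not writable: {d}") from err

    paths = {
        "signals": d / "signals.h5",
        "events": d / "events.tsv",
        "textgrid": d / "annotations.TextGrid",
        "electrodes": d / "electrodes.tsv",
        "config": d / "config.json",
        "ground_truth": d / "ground_truth.json",
    }
    rec, kin = session.recording, session.kinematics
    with h5py.File(paths["signals"], "w") as f:
        g = f.create_dataset("lfp", data=rec.data)
        g.attrs["fs"] = rec.fs
        g.attrs["ch_names"] = [str(c) for c in rec.ch_names]
        k = f.create_dataset("kinematics", data=kin.data)
        k.attrs["fs"] = kin.fs
        k.attrs["names"] = [str(c) for c in kin.names]
    session.events.df.to_csv(paths["events"], sep="\t", index=False)
    write_textgrid(session.events, paths["textgrid"], rec.duration_s)
    pd.DataFrame({
        "name": rec.ch_names,
        "x": rec.coords_mm[:, 0], "y": rec.coords_mm[:, 1], "z": rec.coords_mm[:, 2],
        "region": rec.regions, "responsive": rec.responsive.astype(int),
    }).to_csv(paths["electrodes"], sep="\t", index=False)
    if session.config is not None:
        cfg = dataclasses.asdict(session.config)
        paths["config"].write_text(json.dumps(_jsonable(cfg), indent=1))
    paths["ground_truth"].write_text(
        json.dumps(_jsonable(session.ground_truth), indent=1))
    return {k: str(v) for k, v in paths.items()}


def read_session(directory) -> SyntheticSession:
    """Round-trip reader for :func:`write_session` output."""
    d = Path(directory)
    with h5py.File(d / "signals.h5", "r") as f:
        lfp = f["lfp"][()]
        fs_lfp = float(f["lfp"].attrs["fs"])
        ch_names = [str(c) for c in f["lfp"].attrs["ch_names"]]
        kin_data = f["kinematics"][()]
        fs_kin = float(f["kinematics"].attrs["fs"])
        kin_names = [str(c) for c in f["kinematics"].attrs["names"]]
    elec = pd.read_csv(d / "electrodes.tsv", sep="\t")
    rec = Recording(data=lfp, fs=fs_lfp, ch_names=ch_names,
                    coords_mm=elec[["x", "y", "z"]].to_numpy(),
                    regions=list(elec["region"]),
                    responsive=elec["responsive"].to_numpy(dtype=bool))
    kin = TractKinematics(kin_data, fs_kin, kin_names)
    events = EventTable(pd.read_csv(d / "events.tsv", sep="\t",
                                    keep_default_na=False,
                                    na_values=[""]))
    gt_path = d / "ground_truth.json"
    gt = json.loads(gt_path.read_text()) if gt_path.exists() else {}
    cfg_path = d / "config.json"
    cfg = None
    if cfg_path.exists():
        raw = json.loads(cfg_path.read_text())
        if raw.get("channel_phase_offsets") is not None:
            raw["channel_phase_offsets"] = np.asarray(raw["channel_phase_offsets"])
        cfg = SessionConfig(**raw)
    return SyntheticSession(recording=rec, kinematics=kin, events=events,
                            ground_truth=gt, config=cfg)
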