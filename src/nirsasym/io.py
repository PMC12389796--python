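"""SNIRF (HDF5) and CSV input-output.

Recordings are exchanged in the SNIRF v1.1 layout: continuous-wave
amplitudes under ``/nirs/data1`` with one measurementList entry per
(channel, wavelength), probe wavelengths/labels/positions under
``/nirs/probe`` and one stimulus group per phase label under
``/nirs/stim*``.  Cue onsets travel as a zero-duration ``cue`` stimulus
group.  The writer and reader are symmetric; an independent SNIRF reader
is used as a cross-check in the test-suite.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import yaml

from .montage_events import EventSchedule, Montage, Phase
from .synthetic_cohort import ResponseScenario, SyntheticRecording

_STR = h5py.string_dtype(encoding="utf-8")


def _optode_layout(montage: Montage):
    sources: list[str] = []
    detectors: list[str] = []
    for ch in montage.channels:
        src, det = ch.split("-", 1)
        if src not in sources:
            sources.append(src)
        if det not in detectors:
            detectors.append(det)
    pos = montage.positions or {}

    def optode_pos(name: str, role: int) -> tuple[float, float]:
        pts = [
            pos[ch]
            for ch in montage.channels
            if ch in pos and ch.split("-", 1)[role] == name
        ]
        if not pts:
            return (0.0, 0.0)
        arr = np.asarray(pts, float)
        return (float(arr[:, 0].mean()), float(arr[:, 1].mean()))

    spos = np.array([optode_pos(s, 0) for s in sources])
    dpos = np.array([optode_pos(d, 1) for d in detectors])
    return sources, detectors, spos, dpos


def write_snirf(
    path,
    recording: SyntheticRecording,
    montage: Montage,
    subject_id: str = "S01",
) -> None:
    """Write a raw-intensity recording as a SNIRF v1.1 file."""
    if recording.intensities is None:
        raise ValueError("recording has no intensity data; call to_intensities first")
    n_ch = len(recording.channels)
    n_t = recording.intensities.shape[2]
    sources, detectors, spos, dpos = _optode_layout(montage)
    src_idx = {s: i + 1 for i, s in enumerate(sources)}
    det_idx = {d: i + 1 for i, d in enumerate(detectors)}

    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.1", dtype=_STR)
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        for k, v in {
            "SubjectID": subject_id,
            "MeasurementDate": "2000-01-01",
            "MeasurementTime": "00:00:00",
            "LengthUnit": "m",
            "TimeUnit": "s",
            "FrequencyUnit": "Hz",
        }.items():
            meta.create_dataset(k, data=v, dtype=_STR)

        data = nirs.create_group("data1")
        # columns: all channels at wavelength 1, then all at wavelength 2
        ts = np.concatenate(
            [recording.intensities[:, 0, :].T, recording.intensities[:, 1, :].T], axis=1
        )
        data.create_dataset("dataTimeSeries", data=ts)
        data.create_dataset("time", data=np.arange(n_t) / recording.fs)
        for w in (0, 1):
            for i, ch in enumerate(recording.channels):
                src, det = ch.split("-", 1)
                ml = data.create_group(f"measurementList{w * n_ch + i + 1}")
                ml.create_dataset("sourceIndex", data=src_idx[src], dtype="int32")
                ml.create_dataset("detectorIndex", data=det_idx[det], dtype="int32")
                ml.create_dataset("wavelengthIndex", data=w + 1, dtype="int32")
                ml.create_dataset("dataType", data=1, dtype="int32")  # CW amplitude
                ml.create_dataset("dataTypeIndex", data=1, dtype="int32")

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(recording.wavelengths, float))
        probe.create_dataset("sourcePos2D", data=spos)
        probe.create_dataset("detectorPos2D", data=dpos)
        probe.create_dataset("sourcePos3D", data=np.column_stack([spos, np.zeros(len(spos))]))
        probe.create_dataset("detectorPos3D", data=np.column_stack([dpos, np.zeros(len(dpos))]))
        probe.create_dataset("sourceLabels", data=np.array(sources, dtype=_STR))
        probe.create_dataset("detectorLabels", data=np.array(detectors, dtype=_STR))

        sched = recording.schedule
        groups: dict[str, list[tuple[float, float]]] = {}
        for p in sched.phases:
            groups.setdefault(p.label, []).append((p.onset, p.duration))
        i = 1
        for label in sorted(groups):
            st = nirs.create_group(f"stim{i}")
            st.create_dataset("name", data=label, dtype=_STR)
            rows = np.array([(on, du, 1.0) for on, du in groups[label]])
            st.create_dataset("data", data=rows)
            i += 1
        if sched.cue_onsets:
            st = nirs.create_group(f"stim{i}")
            st.create_dataset("name", data="cue", dtype=_STR)
            rows = np.array([(t, 0.0, 1.0) for t, _ in sched.cue_onsets])
            st.create_dataset("data", data=rows)


def _read_str(ds) -> str:
    v = ds[()]
    if isinstance(v, bytes):
        return v.decode()
    if isinstance(v, np.ndarray):
        v = v.item()
        if isinstance(v, bytes):
            return v.decode()
    return str(v)


def read_snirf(path, stim_name_map: dict[str, str] | None = None):
    """Read a SNIRF file back into (intensities, schedule, montage skeleton).

    Returns a dict with keys ``intensities`` (n_channels, n_wavelengths,
    n_times), ``channels``, ``wavelengths``, ``fs``, ``schedule`` and
    ``montage`` (a :class:`Montage` skeleton without symmetric pairs).
    ``stim_name_map`` renames stimulus groups to phase labels; unknown
    names are kept verbatim.
    """
    import warnings

    path = Path(path)
    with h5py.File(path, "r") as f:
        nirs = f["nirs"]
        data = nirs["data1"]
        ts = np.asarray(data["dataTimeSeries"])
        time = np.asarray(data["time"])
        if len(time) < 2:
            raise ValueError("time vector too short")
        fs = 1.0 / float(np.median(np.diff(time)))
        probe = nirs["probe"]
        wavelengths = tuple(float(w) for w in np.asarray(probe["wavelengths"]))
        sources = [s.decode() if isinstance(s, bytes) else str(s) for s in probe["sourceLabels"]]
        detectors = [d.decode() if isinstance(d, bytes) else str(d) for d in probe["detectorLabels"]]

        ml_names = sorted(
            (k for k in data.keys() if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList"):]),
        )
        entries = []
        for k in ml_names:
            g = data[k]
            entries.append(
                (
                    int(g["sourceIndex"][()]),
                    int(g["detectorIndex"][()]),
                    int(g["wavelengthIndex"][()]),
                )
            )
        channels: list[str] = []
        for s, d, w in entries:
            name = f"{sources[s - 1]}-{detectors[d - 1]}"
            if w == 1:
                channels.append(name)
        n_ch = len(channels)
        n_wl = len(wavelengths)
        if ts.shape[1] != n_ch * n_wl:
            raise ValueError("dataTimeSeries width does not match measurement list")
        inten = np.empty((n_ch, n_wl, ts.shape[0]))
        col_of = {}
        for col, (s, d, w) in enumerate(entries):
            name = f"{sources[s - 1]}-{detectors[d - 1]}"
            col_of[(name, w)] = col
        missing = [
            ch for ch in channels for w in range(1, n_wl + 1) if (ch, w) not in col_of
        ]
        if missing:
            raise ValueError(f"channels missing a wavelength: {sorted(set(missing))}")
        for i, ch in enumerate(channels):
            for w in range(n_wl):
                inten[i, w] = ts[:, col_of[(ch, w + 1)]]

        name_map = stim_name_map or {}
        phases: list[Phase] = []
        cues: list[tuple[float, str]] = []
        for k in sorted(k for k in nirs.keys() if k.startswith("stim")):
            g = nirs[k]
            label = _read_str(g["name"])
            label = name_map.get(label, label)
            rows = np.atleast_2d(np.asarray(g["data"]))
            if label == "cue":
                cues.extend((float(r[0]), "cue") for r in rows)
                continue
            for r in rows:
                phases.append(Phase(float(r[0]), float(r[1]), label))
        phases.sort(key=lambda p: p.onset)
        schedule = EventSchedule(phases=phases, cue_onsets=sorted(cues), fs=fs)

        montage = Montage(
            name=path.stem,
            channels=channels,
            hemisphere_of_channel={ch: "left" for ch in channels},
            symmetric_pairs=[],
        )
    return {
        "intensities": inten,
        "channels": channels,
        "wavelengths": wavelengths,
        "fs": fs,
        "schedule": schedule,
        "montage": montage,
    }


def write_truth_sidecar(path, scenario: ResponseScenario) -> None:
    """YAML sidecar with the planted amplitudes and noise settings."""
    payload = {
        "seed": scenario.seed,
        "noise": {
            "white_sd": scenario.noise.white_sd,
            "drift_sd": scenario.noise.drift_sd,
            "mayer_amp": scenario.noise.mayer_amp,
            "resp_amp": scenario.noise.resp_amp,
            "cardiac_amp": scenario.noise.cardiac_amp,
        },
        "amplitude": {
            f"{ch}|{task}|{chrom}": float(v)
            for (ch, task, chrom), v in sorted(scenario.amplitude.items())
        },
        "daily_slope": {
            f"{ch}|{task}|{chrom}": float(v)
            for (ch, task, chrom), v in sorted(scenario.daily_slope.items())
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
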