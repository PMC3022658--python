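"""Hierarchical containers and external-format adapters.

Evoked potentials (plus ground-truth segment tables for synthetic cohorts)
travel between pipeline stages in a single HDF5 file per cohort:

    /evoked/<subject>/<condition>/data   channels x samples, uV
    /truth                               ground-truth segment table (columns)
    /montage                             labels + unit-sphere positions

Real raw EEG (EDF / BrainVision) can be imported through :func:`import_raw`,
a thin adapter around MNE kept isolated here so the rest of the package has
no MNE dependency.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .montage import Montage
from .preprocess import Evoked

__all__ = ["write_eeg_container", "read_eeg_container", "import_raw"]


def write_eeg_container(
    path,
    evokeds: list[Evoked],
    truth: pd.DataFrame | None = None,
    montage: Montage | None = None,
) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for ev in evokeds:
            g = f.create_group(f"evoked/{ev.subject}/{ev.condition}")
            g.create_dataset("data", data=ev.data)
            g.attrs["sfreq"] = ev.sfreq
            g.attrs["reference"] = ev.reference
            g.attrs["log"] = "\n".join(ev.log)
        if truth is not None:
            g = f.create_group("truth")
            for col in truth.columns:
                vals = truth[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype("S")
                g.create_dataset(col, data=vals)
            g.attrs["columns"] = list(truth.columns)
        if montage is not None:
            g = f.create_group("montage")
            g.create_dataset("labels", data=np.array(montage.labels, dtype="S"))
            g.create_dataset("positions", data=montage.positions)


def read_eeg_container(path):
    """Returns ``(evokeds, truth or None, montage or None)``."""
    import h5py

    evokeds, truth, montage = [], None, None
    with h5py.File(path, "r") as f:
        for subj in sorted(f["evoked"]):
            for cond in f[f"evoked/{subj}"]:
                g = f[f"evoked/{subj}/{cond}"]
                evokeds.append(
                    Evoked(
                        data=g["data"][()],
                        sfreq=float(g.attrs["sfreq"]),
                        condition=cond,
                        subject=subj,
                        reference=str(g.attrs.get("reference", "recording")),
                        log=tuple(str(g.attrs.get("log", "")).split("\n")),
                    )
                )
        if "truth" in f:
            cols = list(f["truth"].attrs["columns"])
            data = {}
            for col in cols:
                vals = f["truth"][col][()]
                if vals.dtype.kind == "S":
                    vals = vals.astype(str)
                data[col] = vals
            truth = pd.DataFrame(data)
        if "montage" in f:
            labels = tuple(s.decode() for s in f["montage/labels"][()])
            montage = Montage(labels, f["montage/positions"][()])
    return evokeds, truth, montage


def import_raw(path):
    """Load a raw EEG file (EDF or BrainVision header) via MNE.

    Returns ``(data_uV, sfreq, channel_names)``.  Requires the optional
    ``mne`` dependency.
    """
    import mne  # optional adapter dependency

    path = str(path)
    if path.lower().endswith(".edf"):
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif path.lower().endswith(".vhdr"):
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    else:
        raise ValueError("supported raw formats: .edf, .vhdr")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)
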