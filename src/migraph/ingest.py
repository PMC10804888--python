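"""Optional ingest of user-supplied motor-imagery recordings (GDF format).

Entirely optional: nothing here is imported by the rest of the package,
no data is ever downloaded, and the ``mne`` dependency is only required
when this module's functions are actually called.  Expected directory
layout: one ``A0?T.gdf`` file per subject (first session), 22 EEG
channels plus 3 EOG channels (dropped), 250 Hz, cue-aligned trials.

Epoching convention: half-open sample window ``[start*fs, end*fs)``
relative to each trial start, 0-based; the default window [2 s, 6 s)
captures the 4-s motor-imagery period that begins at the cue (t = 2 s).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .data import TrialSet
from .montage import build_layout

__all__ = ["ingest_bci2a"]

_EVENT_CODES = {769: 0, 770: 1, 771: 2, 772: 3}  # left hand, right hand, feet, tongue
_CLASS_NAMES = ("left_hand", "right_hand", "feet", "tongue")


def ingest_bci2a(directory, epoch_window: tuple[float, float] = (2.0, 6.0),
                 montage: str = "bci2a-22") -> TrialSet:
    """Load first-session GDF recordings from ``directory`` into a TrialSet.

    Raises a clear error (never downloads) when files are missing.
    """
    try:
        import mne
    except ImportError as err:  # pragma: no cover - depends on optional extra
        raise ImportError(
            "reading GDF recordings requires the optional 'mne' dependency: "
            "pip install migraph[gdf]"
        ) from err

    directory = Path(directory)
    files = sorted(directory.glob("A0?T.gdf"))
    if not files:
        raise FileNotFoundError(
            f"no A0?T.gdf recordings found in {directory}; place the first-session "
            "GDF files there (they must be obtained separately; nothing is downloaded)"
        )
    layout = build_layout(montage)
    start_s, end_s = epoch_window
    sig_list, label_list, subject_list = [], [], []
    for subject, path in enumerate(files):
        raw = mne.io.read_raw_gdf(path, preload=True, verbose="error")
        raw.pick(picks="eeg")  # drop EOG
        fs = raw.info["sfreq"]
        events, event_id = mne.events_from_annotations(raw, verbose="error")
        code_of = {v: int(k) for k, v in event_id.items()}
        data = raw.get_data()
        n0, n1 = int(round(start_s * fs)), int(round(end_s * fs))
        for onset, _, eid in events:
            code = code_of.get(eid)
            if code not in _EVENT_CODES:
                continue
            seg = data[:, onset + n0 : onset + n1]
            if seg.shape[1] != n1 - n0:
                continue  # truncated trailing trial
            sig_list.append(seg * 1e6)  # volts -> microvolts
            label_list.append(_EVENT_CODES[code])
            subject_list.append(subject)
    if not sig_list:
        raise ValueError("no cue-aligned trials found in the provided recordings")
    signals = np.stack(sig_list).astype(np.float32)
    if signals.shape[1] != layout.n_channels:
        raise ValueError(
            f"recordings have {signals.shape[1]} EEG channels; montage {montage!r} "
            f"expects {layout.n_channels}"
        )
    return TrialSet(
        signals=signals,
        labels=np.array(label_list),
        fs=float(fs),
        channel_names=layout.channels,
        subject_ids=np.array(subject_list),
        class_names=_CLASS_NAMES,
        provenance={"ingest": "bci2a-gdf", "epoch_window_s": [start_s, end_s],
                    "files": [p.name for p in files]},
    )
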