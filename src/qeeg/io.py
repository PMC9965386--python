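"""EDF/EDF+ input and output for 19-channel recordings.

Reading goes through MNE's EDF reader; channel names are normalised to the
classic 10-20 labels on read (modern T7/T8/P7/P8 aliases map to T3/T4/
T5/T6), and EDF+ annotations become :class:`~qeeg.core.Annotation` records.

Writing uses a small built-in EDF+C writer (16-bit samples, physical range
+-1000 uV, 1-s data records, one "EDF Annotations" signal carrying the
annotation list) so that synthetic cohorts can be exported to a format any
EEG toolchain can open.
"""

from __future__ import annotations

import numpy as np
import mne

from .core import Annotation, EEGRecording, Montage1020, build_standard_montage

#: Modern-nomenclature aliases normalised on read.
CHANNEL_ALIASES = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}


def _normalise_name(raw_name: str) -> str:
    name = raw_name.replace("EEG", "").replace("-REF", "").strip()
    name = name[0].upper() + name[1:] if name else name
    # canonical capitalisation: Fp1, Fz, ...
    if name.upper().endswith("Z"):
        name = name[:-1] + "z"
    if name.lower().startswith("fp"):
        name = "Fp" + name[2:]
    return CHANNEL_ALIASES.get(name, name)


def read_recording(path, montage: Montage1020 | None = None,
                   subject_id: str = "", group: str | None = None
                   ) -> EEGRecording:
    """Load an EDF/EDF+ file into a recording (microvolts)."""
    montage = montage or build_standard_montage()
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    names = {old: _normalise_name(old) for old in raw.ch_names}
    raw.rename_channels(names)
    missing = [c for c in montage.channel_names if c not in raw.ch_names]
    if missing:
        raise ValueError(f"EDF file {path} is missing channels: {missing}")
    raw.reorder_channels(list(montage.channel_names))
    data = raw.get_data() * 1e6  # Volts -> microvolts
    anns = [
        Annotation(str(d), float(o), float(du))
        for o, du, d in zip(raw.annotations.onset, raw.annotations.duration,
                            raw.annotations.description)
    ]
    return EEGRecording(samples=data, fs=float(raw.info["sfreq"]),
                        montage=montage, annotations=anns,
                        subject_id=subject_id or str(path), group=group)


# ---------------------------------------------------------------------------
# Minimal EDF+C writer
# ---------------------------------------------------------------------------

_PHYS_RANGE = 1000.0  # +- physical range in microvolts
_ANN_SAMPLES = 120  # 2-byte samples reserved per record for annotations


def _fixed(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: EEGRecording, path) -> None:
    """Write a recording as 16-bit EDF+C with annotations.

    Samples are clipped to +-1000 uV and quantised to 16 bits; the
    recording is padded with zeros to a whole number of 1-s data records.
    """
    fs = rec.fs
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF export requires an integer sampling frequency")
    n_ch = rec.n_channels
    n_rec = int(np.ceil(rec.n_samples / spr))
    ns = n_ch + 1  # plus the annotations signal

    header = b"".join([
        _fixed("0", 8),
        _fixed(f"X X X {rec.subject_id or 'X'}", 80),
        _fixed("Startdate X X X X", 80),
        _fixed("01.01.00", 8), _fixed("00.00.00", 8),
        _fixed(str(256 * (ns + 1)), 8),
        _fixed("EDF+C", 44),
        _fixed(str(n_rec), 8), _fixed("1", 8), _fixed(str(ns), 4),
    ])
    labels = [_fixed(f"EEG {c}", 16) for c in rec.montage.channel_names]
    labels.append(_fixed("EDF Annotations", 16))

    def per_signal(values):
        return b"".join(values)

    header += per_signal(labels)
    header += per_signal([_fixed("", 80)] * ns)  # transducer
    header += per_signal([_fixed("uV", 8)] * n_ch + [_fixed("", 8)])
    header += per_signal([_fixed(str(-_PHYS_RANGE), 8)] * n_ch
                         + [_fixed("-32768", 8)])
    header += per_signal([_fixed(str(_PHYS_RANGE), 8)] * n_ch
                         + [_fixed("32767", 8)])
    header += per_signal([_fixed("-32768", 8)] * ns)
    header += per_signal([_fixed("32767", 8)] * ns)
    header += per_signal([_fixed("", 80)] * ns)  # prefiltering
    header += per_signal([_fixed(str(spr), 8)] * n_ch
                         + [_fixed(str(_ANN_SAMPLES), 8)])
    header += per_signal([_fixed("", 32)] * ns)

    # physical -> digital
    x = np.clip(rec.samples, -_PHYS_RANGE, _PHYS_RANGE)
    dig = np.round(x / _PHYS_RANGE * 32767.0).astype("<i2")
    pad = n_rec * spr - rec.n_samples
    if pad:
        dig = np.pad(dig, ((0, 0), (0, pad)))

    # annotations grouped into the record containing their onset
    by_record: dict[int, list[Annotation]] = {}
    for ann in rec.annotations:
        by_record.setdefault(int(ann.onset), []).append(ann)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            fh.write(dig[:, r * spr:(r + 1) * spr].tobytes(order="C"))
            tal = f"+{r}\x14\x14\x00".encode("ascii")
            for ann in by_record.get(r, []):
                tal += (f"+{ann.onset:.3f}\x15{ann.duration:.3f}\x14"
                        f"{ann.label}\x14\x00").encode("utf-8")
            if len(tal) > 2 * _ANN_SAMPLES:
                raise ValueError(
                    f"too many annotations in second {r} for the reserved "
                    f"annotation capacity")
            fh.write(tal + b"\x00" * (2 * _ANN_SAMPLES - len(tal)))
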