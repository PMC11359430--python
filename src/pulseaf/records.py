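"""PPG record container and plain-text I/O.

A record is a single-channel photoplethysmogram: one sample per line in the
CSV representation, preceded by ``# key=value`` header lines carrying the
sampling rate, rhythm label and provenance.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

#: Recognised rhythm labels.  ``AF`` — atrial fibrillation, ``NSR`` — normal
#: sinus rhythm, ``unknown`` — unlabeled input.
LABELS = ("AF", "NSR", "unknown")


@dataclass
class PPGRecord:
    """A single-channel PPG waveform with its sampling rate and rhythm label."""

    samples: np.ndarray
    fs_hz: float = 125.0
    rhythm_label: str = "unknown"
    record_id: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D vector")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.fs_hz <= 0:
            raise ValueError(f"fs_hz must be positive, got {self.fs_hz}")
        if self.rhythm_label not in LABELS:
            raise ValueError(f"rhythm_label must be one of {LABELS}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz

    def with_samples(self, samples: np.ndarray) -> "PPGRecord":
        """Copy of this record carrying new samples (label and fs propagate)."""
        return replace(self, samples=np.asarray(samples, dtype=float))


def write_record_csv(record: PPGRecord, path: str | os.PathLike) -> None:
    """Write one sample per line with a ``# key=value`` header block."""
    with open(path, "w") as fh:
        fh.write(f"# fs_hz={record.fs_hz!r}\n")
        fh.write(f"# label={record.rhythm_label}\n")
        fh.write(f"# record_id={record.record_id}\n")
        if record.seed is not None:
            fh.write(f"# seed={record.seed}\n")
        for v in record.samples:
            fh.write(f"{float(v)!r}\n")


def read_record_csv(path: str | os.PathLike) -> PPGRecord:
    """Read a record written by :func:`write_record_csv` (bit-exact round trip)."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"record file not found: {path}")
    meta: dict[str, str] = {}
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            try:
                values.append(float(line))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: not a number: {line!r}") from exc
    if not values:
        raise ValueError(f"{path}: no samples found")
    seed = int(meta["seed"]) if "seed" in meta else None
    return PPGRecord(
        samples=np.array(values, dtype=float),
        fs_hz=float(meta.get("fs_hz", 125.0)),
        rhythm_label=meta.get("label", "unknown"),
        record_id=meta.get("record_id", ""),
        seed=seed,
    )
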