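"""Core time-series containers shared across the pipeline.

A :class:`Trajectory` is the per-molecule fluorescence intensity time series
that every smTIRFM stage consumes: frames acquired at a fixed interval
(100 ms by convention for these experiments), intensities in arbitrary
camera units (AU).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class Trajectory:
    """Per-molecule fluorescence intensity time series.

    Parameters
    ----------
    intensities : ndarray
        Intensity per frame, AU. Must be finite.
    frame_interval : float
        Seconds per frame (exposure + readout), > 0.
    molecule_id : str
        Identifier carried through to dwell tables and reports.
    channel : str
        Emission channel, "Cy3" or "Cy5".
    source : str
        Provenance: "simulated", "movie" or "file".
    """

    intensities: np.ndarray
    frame_interval: float
    molecule_id: str = "mol-0"
    channel: str = "Cy3"
    source: str = "simulated"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1:
            raise ValueError("intensities must be a 1-D array")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.intensities.size

    def __len__(self) -> int:
        return self.intensities.size

    @property
    def times(self) -> np.ndarray:
        """Frame start times in seconds."""
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval

    def trimmed(self, pre_frames: int) -> "Trajectory":
        """Analysis segment with the pre-injection frames removed."""
        if not 0 <= pre_frames < self.n_frames:
            raise ValueError(
                f"pre_frames={pre_frames} outside trajectory of {self.n_frames} frames"
            )
        return dataclasses.replace(self, intensities=self.intensities[pre_frames:])

    # -- plain-text I/O ----------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV with columns frame, time_s, intensity_AU."""
        df = pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "time_s": self.times,
                "intensity_AU": self.intensities,
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        frame_interval: float | None = None,
        **kwargs,
    ) -> "Trajectory":
        df = pd.read_csv(path, sep="\t")
        if frame_interval is None:
            t = df["time_s"].to_numpy()
            if len(t) < 2:
                raise ValueError("cannot infer frame_interval from a 1-frame file")
            frame_interval = float(t[1] - t[0])
        kwargs.setdefault("molecule_id", Path(path).stem)
        kwargs.setdefault("source", "file")
        return cls(df["intensity_AU"].to_numpy(), frame_interval, **kwargs)


def write_manifest(trajs: list[Trajectory], directory: str | Path) -> Path:
    """Write one TSV per molecule plus a manifest CSV; return manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for traj in trajs:
        fname = f"{traj.molecule_id}.tsv"
        traj.to_tsv(directory / fname)
        rows.append(
            {
                "molecule_id": traj.molecule_id,
                "file": fname,
                "n_frames": traj.n_frames,
                "frame_interval_s": traj.frame_interval,
                "channel": traj.channel,
                "source": traj.source,
            }
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_manifest(directory: str | Path) -> list[Trajectory]:
    """Load every trajectory listed in a directory's manifest CSV."""
    directory = Path(directory)
    manifest = directory / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.csv in {directory}")
    df = pd.read_csv(manifest)
    out = []
    for row in df.itertuples():
        out.append(
            Trajectory.from_tsv(
                directory / row.file,
                frame_interval=row.frame_interval_s,
                molecule_id=row.molecule_id,
                channel=row.channel,
            )
        )
    return out


@dataclass
class FretTrace:
    """Donor/acceptor intensity pair for one surface-tethered molecule."""

    donor: np.ndarray
    acceptor: np.ndarray
    molecule_id: str = "mol-0"
    frame_interval: float = 0.1

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.shape != self.acceptor.shape or self.donor.ndim != 1:
            raise ValueError("donor and acceptor must be equal-length 1-D arrays")
        if not (np.all(np.isfinite(self.donor)) and np.all(np.isfinite(self.acceptor))):
            raise ValueError("channel intensities must be finite")

    def __len__(self) -> int:
        return self.donor.size


@dataclass
class MovieStack:
    """TIRF movie: a (frame, y, x) grayscale stack with acquisition metadata."""

    frames: np.ndarray
    frame_interval: float = 0.1
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (n_frames, y, x) stack with >= 1 frame")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def to_tiff(self, path: str | Path) -> None:
        import tifffile

        tifffile.imwrite(str(path), self.frames.astype(np.float32))

    @classmethod
    def from_tiff(cls, path: str | Path, frame_interval: float = 0.1) -> "MovieStack":
        import tifffile

        frames = np.asarray(tifffile.imread(str(path)), dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
        return cls(frames, frame_interval)
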