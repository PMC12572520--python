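"""Named, ordered 3D point sets (bony landmarks, fracture sites) with JSON/CSV I/O."""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .errors import PairingError, ParameterError

__all__ = ["LandmarkSet", "FracturePoint"]

_FRAMES = ("model", "patient")


@dataclass
class LandmarkSet:
    """Ordered, named 3D points in millimetres.

    Order is significant: index ``i`` of a model-frame set corresponds to
    index ``i`` of a patient-frame set when the two are registered.
    """

    names: list[str]
    points: np.ndarray
    frame: str = "model"

    def __post_init__(self) -> None:
        self.names = list(self.names)
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape != (len(self.names), 3):
            raise ParameterError(
                f"points shape {self.points.shape} does not match {len(self.names)} names"
            )
        if len(set(self.names)) != len(self.names):
            raise ParameterError("landmark names must be unique")
        if self.frame not in _FRAMES:
            raise ParameterError(f"frame must be one of {_FRAMES}, got {self.frame!r}")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self) -> Iterator[tuple[str, np.ndarray]]:
        return iter(zip(self.names, self.points))

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.points[self.names.index(name)]
        except ValueError:
            raise KeyError(name) from None

    def with_points(self, points: np.ndarray, frame: str | None = None) -> "LandmarkSet":
        return LandmarkSet(list(self.names), points, frame or self.frame)

    def subset(self, names: Iterable[str]) -> "LandmarkSet":
        names = list(names)
        idx = [self.names.index(n) for n in names]
        return LandmarkSet(names, self.points[idx], self.frame)

    def check_paired_with(self, other: "LandmarkSet") -> None:
        """Raise :class:`PairingError` unless both sets list the same names in order."""
        if len(self) != len(other):
            raise PairingError(f"landmark counts differ: {len(self)} vs {len(other)}")
        if self.names != other.names:
            raise PairingError(
                f"landmark names/order differ: {self.names} vs {other.names}"
            )

    # ------------------------------------------------------------------ I/O
    def to_records(self) -> list[dict]:
        return [
            {"name": n, "x_mm": float(p[0]), "y_mm": float(p[1]), "z_mm": float(p[2]), "frame": self.frame}
            for n, p in self
        ]

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_records(), indent=2) + "\n")

    def save_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=["name", "x_mm", "y_mm", "z_mm", "frame"])
            w.writeheader()
            w.writerows(self.to_records())

    @classmethod
    def from_records(cls, records: list[dict]) -> "LandmarkSet":
        frames = {r.get("frame", "model") for r in records}
        if len(frames) != 1:
            raise ParameterError(f"records mix frames: {sorted(frames)}")
        return cls(
            [r["name"] for r in records],
            np.array([[r["x_mm"], r["y_mm"], r["z_mm"]] for r in records], dtype=float),
            frames.pop(),
        )

    @classmethod
    def load_json(cls, path: str | Path) -> "LandmarkSet":
        return cls.from_records(json.loads(Path(path).read_text()))

    @classmethod
    def load_csv(cls, path: str | Path) -> "LandmarkSet":
        with open(path, newline="") as fh:
            rows = [
                {**r, "x_mm": float(r["x_mm"]), "y_mm": float(r["y_mm"]), "z_mm": float(r["z_mm"])}
                for r in csv.DictReader(fh)
            ]
        return cls.from_records(rows)


@dataclass
class FracturePoint:
    """A simulated fracture site on a rib centerline."""

    name: str
    point: np.ndarray
    rib_index: int
    side: str  # "left" | "right"

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        if self.point.shape != (3,):
            raise ParameterError(f"fracture point must be a 3-vector, got {self.point.shape}")
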