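"""Oocyte annotation: outline polygon and anteroposterior axis.

Coordinates are in micrometres with the origin at the lower-left of the
field; the anterior and posterior poles define the AP axis along which
signal distributions are quantified.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from matplotlib.path import Path as MplPath

from stau_rnaloc.errors import InvalidParameterError


@dataclass(frozen=True)
class OocyteAnnotation:
    """Closed outline polygon plus the two AP-axis pole points.

    Parameters
    ----------
    outline
        ``(n, 2)`` array of polygon vertices in µm. The polygon is
        implicitly closed (last vertex connects back to the first) and
        must be simple (non-self-intersecting).
    anterior, posterior
        2-D pole points in µm; both must lie on or inside the outline
        and must differ.
    """

    outline: np.ndarray
    anterior: np.ndarray
    posterior: np.ndarray
    _path: MplPath = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        outline = np.asarray(self.outline, dtype=float)
        anterior = np.asarray(self.anterior, dtype=float)
        posterior = np.asarray(self.posterior, dtype=float)
        if outline.ndim != 2 or outline.shape[1] != 2 or outline.shape[0] < 3:
            raise InvalidParameterError(
                f"outline must be an (n>=3, 2) array, got shape {outline.shape}"
            )
        if not np.all(np.isfinite(outline)):
            raise InvalidParameterError("outline contains non-finite coordinates")
        if anterior.shape != (2,) or posterior.shape != (2,):
            raise InvalidParameterError("poles must be 2-D points")
        if np.allclose(anterior, posterior):
            raise InvalidParameterError("anterior and posterior poles coincide")
        if _is_self_intersecting(outline):
            raise InvalidParameterError("outline polygon is self-intersecting")
        object.__setattr__(self, "outline", outline)
        object.__setattr__(self, "anterior", anterior)
        object.__setattr__(self, "posterior", posterior)
        object.__setattr__(self, "_path", MplPath(outline, closed=True))
        # radius=1e-9 treats boundary points as inside
        for name, pole in (("anterior", anterior), ("posterior", posterior)):
            if not self.contains(pole[None, :], atol=1e-6)[0]:
                raise InvalidParameterError(f"{name} pole lies outside the outline")

    def contains(self, points: np.ndarray, atol: float = 0.0) -> np.ndarray:
        """Vectorised point-in-polygon test (boundary counts as inside)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        # matplotlib's radius parameter dilates the path slightly so that
        # points exactly on the boundary are accepted
        return self._path.contains_points(pts, radius=max(atol, 1e-9))

    @property
    def axis_length(self) -> float:
        """Euclidean distance between the two poles (µm)."""
        return float(np.linalg.norm(self.posterior - self.anterior))

    @property
    def area(self) -> float:
        """Polygon area (µm²) via the shoelace formula."""
        x, y = self.outline[:, 0], self.outline[:, 1]
        return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        return self.outline.min(axis=0), self.outline.max(axis=0)

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` points uniformly inside the outline (rejection)."""
        lo, hi = self.bounding_box()
        out = np.empty((n, 2))
        filled = 0
        while filled < n:
            m = max(4 * (n - filled), 64)
            cand = rng.uniform(lo, hi, size=(m, 2))
            keep = cand[self.contains(cand)]
            take = min(len(keep), n - filled)
            out[filled : filled + take] = keep[:take]
            filled += take
        return out

    def to_dict(self) -> dict:
        return {
            "outline": self.outline.tolist(),
            "anterior": self.anterior.tolist(),
            "posterior": self.posterior.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OocyteAnnotation":
        return cls(
            outline=np.asarray(d["outline"], dtype=float),
            anterior=np.asarray(d["anterior"], dtype=float),
            posterior=np.asarray(d["posterior"], dtype=float),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "OocyteAnnotation":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _segments_cross(p1, p2, q1, q2) -> bool:
    def orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    d1, d2 = orient(q1, q2, p1), orient(q1, q2, p2)
    d3, d4 = orient(p1, p2, q1), orient(p1, p2, q2)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def _is_self_intersecting(outline: np.ndarray) -> bool:
    """O(n²) proper-crossing test between non-adjacent edges."""
    n = len(outline)
    edges = [(outline[i], outline[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent through the closing edge
            if _segments_cross(*edges[i], *edges[j]):
                return True
    return False
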