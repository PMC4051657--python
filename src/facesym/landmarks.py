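"""Landmark configurations and the bilateral (object) symmetry scheme.

A facial configuration is a fixed, ordered set of named 3D landmarks.  The
default schema is the nine mid-facial landmarks used throughout the package:
left/right *Zygion*, left/right *Alare*, the centers of the two eyeballs, and
three midline landmarks (*Nasion*, *Pronasale*, *Subnasale*).

The :class:`SymmetryScheme` records which landmarks form left/right pairs,
which lie on the midline, and which coordinate axis is flipped by the mirror.
It also provides the reflection-relabeling operator and the induced
symmetric/antisymmetric decomposition of landmark displacement fields, which
is the geometric backbone of the object-symmetry analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical landmark order for the nine mid-facial landmarks.
DEFAULT_LANDMARK_NAMES: tuple[str, ...] = (
    "zygion_left",
    "zygion_right",
    "alare_left",
    "alare_right",
    "eye_left",
    "eye_right",
    "nasion",
    "pronasale",
    "subnasale",
)


@dataclass(frozen=True)
class SymmetryScheme:
    """Left/right pairing structure of a bilaterally symmetric landmark set.

    Parameters
    ----------
    paired_indices
        ``(left, right)`` index pairs into the canonical landmark order.
    midline_indices
        Indices of landmarks lying on the (idealized) midsagittal plane.
    reflection_axis
        The coordinate axis (0, 1 or 2) negated by the mirror; by convention
        axis 0 is the left-right axis.
    """

    paired_indices: tuple[tuple[int, int], ...] = ((0, 1), (2, 3), (4, 5))
    midline_indices: tuple[int, ...] = (6, 7, 8)
    reflection_axis: int = 0

    def __post_init__(self) -> None:
        flat = [i for pair in self.paired_indices for i in pair]
        flat += list(self.midline_indices)
        if len(flat) != len(set(flat)):
            raise ValueError("a landmark index appears more than once in the scheme")
        if sorted(flat) != list(range(len(flat))):
            raise ValueError("scheme indices must cover 0..k-1 exactly")
        if self.reflection_axis not in (0, 1, 2):
            raise ValueError("reflection_axis must be one of 0, 1, 2")

    @property
    def n_landmarks(self) -> int:
        return 2 * len(self.paired_indices) + len(self.midline_indices)

    @property
    def permutation(self) -> np.ndarray:
        """Row permutation swapping left and right labels (midline fixed)."""
        perm = np.arange(self.n_landmarks)
        for left, right in self.paired_indices:
            perm[left], perm[right] = right, left
        return perm

    def validate_landmarks(self, k: int) -> None:
        if k != self.n_landmarks:
            raise ValueError(
                f"scheme covers {self.n_landmarks} landmarks but configuration has {k}"
            )

    def reflect(self, coords: np.ndarray) -> np.ndarray:
        """Mirror coordinates and swap left/right labels.

        Accepts a single ``(k, 3)`` configuration or a batch ``(n, k, 3)``.
        The operation is an involution: applying it twice is the identity.
        """
        coords = np.asarray(coords, dtype=float)
        out = coords[..., self.permutation, :].copy()
        out[..., self.reflection_axis] = -out[..., self.reflection_axis]
        return out

    def symmetric_part(self, v: np.ndarray) -> np.ndarray:
        """Projection of a displacement field onto the symmetric subspace."""
        return (np.asarray(v, dtype=float) + self.reflect(v)) / 2.0

    def antisymmetric_part(self, v: np.ndarray) -> np.ndarray:
        """Projection onto the antisymmetric subspace.

        Antisymmetric fields change sign under reflection-relabeling: mirrored
        landmarks are displaced oppositely and midline landmarks move only off
        the midline plane.  For 3 pairs + 3 midline landmarks the subspace has
        dimension 12.
        """
        return (np.asarray(v, dtype=float) - self.reflect(v)) / 2.0

    def is_symmetric(self, coords: np.ndarray, tol: float = 1e-9) -> bool:
        coords = np.asarray(coords, dtype=float)
        return bool(np.max(np.abs(coords - self.reflect(coords))) <= tol)


#: The default nine-landmark scheme: 3 bilateral pairs + 3 midline landmarks.
DEFAULT_SCHEME = SymmetryScheme()


@dataclass
class LandmarkConfiguration:
    """One individual's named 3D landmark configuration.

    ``coordinates`` is a ``(k, 3)`` array in arbitrary device units; the row
    order follows ``landmark_names`` and must be identical across a dataset.
    """

    individual_id: str
    coordinates: np.ndarray
    landmark_names: tuple[str, ...] = DEFAULT_LANDMARK_NAMES

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (k, 3)")
        if len(self.landmark_names) != self.coordinates.shape[0]:
            raise ValueError("one coordinate triple required per named landmark")
        if len(set(self.landmark_names)) != len(self.landmark_names):
            raise ValueError("landmark names must be unique")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError(
                f"non-finite coordinates for individual {self.individual_id!r}"
            )

    @property
    def n_landmarks(self) -> int:
        return self.coordinates.shape[0]


def stack_configurations(
    configs,
) -> tuple[list[str], np.ndarray]:
    """Stack a collection of configurations into ids and an ``(n, k, 3)`` array.

    Also accepts a bare ``(n, k, 3)`` array, in which case ids are generated.
    """
    if isinstance(configs, np.ndarray):
        arr = np.asarray(configs, dtype=float)
        if arr.ndim != 3:
            raise ValueError("expected an (n, k, 3) array")
        return [f"obs{i:05d}" for i in range(arr.shape[0])], arr
    configs = list(configs)
    if not configs:
        raise ValueError("empty collection of configurations")
    names = configs[0].landmark_names
    for c in configs[1:]:
        if c.landmark_names != names:
            raise ValueError("landmark order must be identical across a dataset")
    ids = [c.individual_id for c in configs]
    return ids, np.stack([c.coordinates for c in configs])


def default_template() -> np.ndarray:
    """A bilaterally symmetric nine-landmark mid-facial template (mm scale).

    Axis 0 is left(+)/right(-), axis 1 vertical, axis 2 out of the face.
    Midline landmarks sit exactly on the x = 0 plane and paired landmarks are
    exact mirror images, so the template is symmetric under the default scheme.
    """
    return np.array(
        [
            [70.0, 0.0, -45.0],   # zygion_left
            [-70.0, 0.0, -45.0],  # zygion_right
            [17.0, -28.0, 12.0],  # alare_left
            [-17.0, -28.0, 12.0], # alare_right
            [33.0, 32.0, 0.0],    # eye_left
            [-33.0, 32.0, 0.0],   # eye_right
            [0.0, 38.0, 5.0],     # nasion
            [0.0, -15.0, 32.0],   # pronasale
            [0.0, -35.0, 18.0],   # subnasale
        ]
    )
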