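"""Trajectory container shared by all solvers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """A single stochastic solution trajectory.

    ``states`` has shape ``(len(times), M_species, N_voxels)`` and holds
    the state recorded at each output time (the state immediately before
    the first event past that time).  ``event_counts`` are diagnostics:
    totals of reaction and diffusion events executed.
    """

    times: np.ndarray
    states: np.ndarray
    species_names: list[str]
    seed: int
    solver: str
    event_counts: dict[str, int] = field(default_factory=dict)
    volumes: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states)
        if self.states.shape[0] != len(self.times):
            raise ValueError("states first axis must match times")

    @property
    def n_species(self) -> int:
        return self.states.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.states.shape[2]

    def species_index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None

    def counts(self, species: str) -> np.ndarray:
        """Per-voxel counts over time, shape (T, N)."""
        return self.states[:, self.species_index(species), :]

    def totals(self, species: str | None = None) -> np.ndarray:
        """Total copy number over time (one species or all summed)."""
        if species is None:
            return self.states.sum(axis=(1, 2))
        return self.counts(species).sum(axis=1)

    def totals_to_csv(self, path) -> None:
        """Write time plus per-species total copy numbers as CSV."""
        cols = np.column_stack([self.times] + [self.totals(s) for s in self.species_names])
        header = ",".join(["time_s"] + self.species_names)
        np.savetxt(path, cols, delimiter=",", header=header, comments="")
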