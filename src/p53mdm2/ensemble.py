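"""Conformational-ensemble analysis: RMSD, radius of gyration, 2D
free-energy surfaces and per-residue helix propensities.

A free-energy surface over two order parameters — the Cα RMSD to a
reference (the bound-form peptide conformation) and the radius of
gyration — is the negative log of the binned population,
F(bin) = −ln(count/total), shifted so the occupied minimum is zero.
Unsampled bins are masked, not assigned a number.

Coordinates are in nanometres; the Cα selection is the default for both
order parameters, with uniform masses for R_g.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import numpy.ma as ma
from scipy.spatial.transform import Rotation

from .geometry import backbone_dihedrals

__all__ = [
    "Ensemble",
    "FESGrid",
    "HELIX_PHI_RANGE_DEG",
    "HELIX_PSI_RANGE_DEG",
    "radius_of_gyration",
    "rmsd_to_reference",
    "build_fes",
    "helix_propensity",
]

#: dihedral window used to call a residue-frame helical, degrees
HELIX_PHI_RANGE_DEG = (-100.0, -30.0)
HELIX_PSI_RANGE_DEG = (-67.0, -7.0)


@dataclass
class Ensemble:
    """Frames of labelled backbone coordinates with a reference frame.

    ``coords`` has shape (n_frames, n_atoms, 3); ``atom_names`` is one
    label per atom ('N', 'CA', 'C', ...), constant across frames.
    """

    coords: np.ndarray
    atom_names: list[str]
    reference: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[1] != len(self.atom_names):
            raise ValueError("atom_names length mismatch")
        if self.reference is not None:
            self.reference = np.asarray(self.reference, dtype=float)
            if self.reference.shape != self.coords.shape[1:]:
                raise ValueError("reference does not match frame shape")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def ca_indices(self) -> np.ndarray:
        idx = np.array([i for i, a in enumerate(self.atom_names)
                        if a == "CA"])
        if idx.size == 0:
            raise ValueError("ensemble has no CA atoms")
        return idx

    def ca_coords(self) -> np.ndarray:
        return self.coords[:, self.ca_indices(), :]


@dataclass
class FESGrid:
    """2D free-energy surface over (RMSD, R_g).

    ``free_energy`` is a masked array (−ln population, occupied minimum
    shifted to 0; unsampled bins masked); ``populations`` sum to 1.
    """

    rmsd_edges: np.ndarray
    rg_edges: np.ndarray
    free_energy: ma.MaskedArray
    populations: np.ndarray


def radius_of_gyration(frame: np.ndarray) -> float:
    """Uniform-mass R_g: RMS distance of the atoms to their centroid."""
    xyz = np.asarray(frame, dtype=float)
    if xyz.ndim != 2 or xyz.shape[0] < 2:
        raise ValueError("need at least 2 atoms")
    centered = xyz - xyz.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))


def rmsd_to_reference(frame: np.ndarray, reference: np.ndarray) -> float:
    """Minimum RMSD after optimal rigid superposition (Kabsch).

    Translation is removed by centering; the optimal proper rotation
    comes from the Kabsch/Wahba solution.
    """
    a = np.asarray(frame, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frame and reference atom sets differ")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    _, rssd = Rotation.align_vectors(b, a)
    return float(rssd / np.sqrt(a.shape[0]))


def order_parameters(ens: Ensemble) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame (RMSD to reference, R_g) over the Cα selection."""
    if ens.reference is None:
        raise ValueError("ensemble has no reference frame")
    idx = ens.ca_indices()
    ref = ens.reference[idx]
    ca = ens.coords[:, idx, :]
    rmsd = np.array([rmsd_to_reference(f, ref) for f in ca])
    rg = np.array([radius_of_gyration(f) for f in ca])
    return rmsd, rg


def build_fes(ens: Ensemble, n_bins_rmsd: int = 50,
              n_bins_rg: int = 50) -> FESGrid:
    """2D histogram of (RMSD, R_g) converted to −ln(population)."""
    if ens.n_frames < 100:
        warnings.warn(f"only {ens.n_frames} frames; surface will be noisy",
                      stacklevel=2)
    rmsd, rg = order_parameters(ens)
    counts, rmsd_edges, rg_edges = np.histogram2d(
        rmsd, rg, bins=[n_bins_rmsd, n_bins_rg])
    pops = counts / counts.sum()
    occupied = pops > 0
    fes = ma.masked_array(np.zeros_like(pops), mask=~occupied)
    fes[occupied] = -np.log(pops[occupied])
    fes -= fes.min()
    return FESGrid(rmsd_edges=rmsd_edges, rg_edges=rg_edges,
                   free_energy=fes, populations=pops)


def helix_propensity(ens: Ensemble,
                     phi_range: tuple[float, float] = HELIX_PHI_RANGE_DEG,
                     psi_range: tuple[float, float] = HELIX_PSI_RANGE_DEG
                     ) -> np.ndarray:
    """Per-residue fraction of frames with helical (φ, ψ).

    A residue-frame is helical iff φ and ψ both fall inside the helix
    window. Terminal residues, whose φ or ψ is undefined, are NaN.
    Requires full N, Cα, C backbones.
    """
    names = ens.atom_names
    if names[:3] != ["N", "CA", "C"] or len(names) % 3:
        raise ValueError("helix propensity needs N, CA, C backbone atoms")
    n_res = len(names) // 3
    helical = np.zeros((ens.n_frames, n_res))
    defined = np.zeros(n_res, dtype=bool)
    for k, frame in enumerate(ens.coords):
        phi, psi = backbone_dihedrals(frame)
        ok = ~(np.isnan(phi) | np.isnan(psi))
        defined |= ok
        helical[k, ok] = ((phi[ok] >= phi_range[0]) & (phi[ok] <= phi_range[1])
                          & (psi[ok] >= psi_range[0])
                          & (psi[ok] <= psi_range[1]))
    prop = helical.mean(axis=0)
    prop[~defined] = np.nan
    return prop
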