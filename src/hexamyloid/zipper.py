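"""Simplified steric-zipper template enumeration and threading.

A steric zipper is the cross-beta core of an amyloid fibril: two facing
beta-sheets whose side chains interdigitate. The simplified 3D-profile
geometry used here starts from a scaffold of two identical five-strand
sheets of a fibril-forming hexapeptide and enumerates rigid-body poses of
the second sheet on a small grid: shifts along the chain direction of
0-8 A in 1 A steps, and sheet separations of 6-11 A in 1 A steps —
9 x 6 = 54 templates (the third direction of the full-profile method is
deliberately not sampled). A query hexapeptide is threaded onto all ten
chains of each template; an external energy adapter (e.g. a wrapper
around a protein design program) supplies per-chain energies, and the
minimum over all templates and chains decides the label against the
-23 kcal/mol threshold.

No structure identifier accompanies the scaffold concept, so the package
ships a *synthetic* idealized parallel in-register beta-sheet scaffold
built from ideal strand geometry (3.5 A rise per residue, 4.8 A strand
spacing, 8.0 A native sheet separation); any user PDB with two annotated
sheets is accepted as an alternative.
"""

from __future__ import annotations

import logging
import string
from collections.abc import Callable, Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBIO, PDBParser
from Bio.PDB.StructureBuilder import StructureBuilder

from .alphabet import AA_THREE, KYTE_DOOLITTLE
from .hexdata import validate_hexapeptide

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C", "O")
N_STRANDS = 5
N_RESIDUES = 6
DEFAULT_SHIFTS = tuple(range(0, 9))  # Angstrom, along the chains
DEFAULT_SEPARATIONS = tuple(range(6, 12))  # Angstrom, across the sheets
CHAIN_IDS = string.ascii_uppercase[: 2 * N_STRANDS]  # A-E sheet 1, F-J sheet 2


@dataclass
class Scaffold:
    """Backbone coordinates of a two-sheet, five-strand-per-sheet scaffold.

    ``coords`` has shape (2, n_strands, n_residues, 4, 3): sheet, strand,
    residue, backbone atom (N, CA, C, O), xyz in Angstrom.
    """

    coords: np.ndarray
    sequence: str = "NNQQNY"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 5 or self.coords.shape[0] != 2 or self.coords.shape[3] != 4:
            raise ValueError(f"scaffold coords must be (2, S, R, 4, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("scaffold coordinates must be finite")

    # -- geometric frame, recomputed from coordinates --

    def ca(self, sheet: int) -> np.ndarray:
        """C-alpha coordinates of one sheet, shape (strands, residues, 3)."""
        return self.coords[sheet, :, :, 1, :]

    def chain_axis(self) -> np.ndarray:
        """Unit mean Ca(i)->Ca(i+1) direction of sheet 1's strands."""
        ca = self.ca(0)
        steps = np.diff(ca, axis=1).reshape(-1, 3)
        axis = steps.mean(axis=0)
        norm = np.linalg.norm(axis)
        if norm < 1e-8:
            raise ValueError("degenerate scaffold: undefined chain axis")
        return axis / norm

    def interstrand_axis(self) -> np.ndarray:
        """Unit mean strand-centroid-to-next-centroid direction, sheet 1."""
        centroids = self.ca(0).mean(axis=1)
        steps = np.diff(centroids, axis=0)
        axis = steps.mean(axis=0)
        norm = np.linalg.norm(axis)
        if norm < 1e-8:
            raise ValueError("degenerate scaffold: undefined inter-strand axis")
        return axis / norm

    def sheet_normal(self) -> np.ndarray:
        """Unit normal to sheet 1, oriented from sheet 1 toward sheet 2."""
        normal = np.cross(self.chain_axis(), self.interstrand_axis())
        norm = np.linalg.norm(normal)
        if norm < 1e-8:
            raise ValueError("degenerate scaffold: chain and inter-strand axes parallel")
        normal = normal / norm
        gap = self.coords[1].reshape(-1, 3).mean(axis=0) - self.coords[0].reshape(-1, 3).mean(axis=0)
        return normal if gap @ normal >= 0 else -normal

    def sheet_separation(self) -> float:
        """Centroid gap between the sheets projected on the sheet normal."""
        normal = self.sheet_normal()
        gap = self.coords[1].reshape(-1, 3).mean(axis=0) - self.coords[0].reshape(-1, 3).mean(axis=0)
        return float(gap @ normal)


def synthetic_ideal_scaffold(
    sequence: str = "NNQQNY",
    rise: float = 3.5,
    strand_spacing: float = 4.8,
    sheet_separation: float = 8.0,
    pleat: float = 0.6,
) -> Scaffold:
    """Build the synthetic idealized beta-sheet scaffold.

    Parallel, in-register strands run along x (one residue per ``rise``),
    strands stack along y at ``strand_spacing``, and the second sheet is
    the first rotated half a turn about x (so the faces oppose) and
    placed ``sheet_separation`` away along z. Geometry is idealized, not
    refined — it exists so the template enumeration and threading can be
    exercised and tested without any external structure.
    """
    validate_hexapeptide(sequence, allow_cysteine=True)
    sheet = np.zeros((N_STRANDS, N_RESIDUES, 4, 3))
    for s in range(N_STRANDS):
        for r in range(N_RESIDUES):
            zig = pleat if r % 2 == 0 else -pleat
            ca = np.array([r * rise, s * strand_spacing, 0.4 * zig])
            n = ca + np.array([-1.25, 0.35 * zig, 0.3])
            c = ca + np.array([1.25, -0.35 * zig, 0.3])
            o = c + np.array([0.25, 1.1, 0.45])
            sheet[s, r] = [n, ca, c, o]
    # rotate the copy 180 degrees about x, then offset along z
    flip = np.diag([1.0, -1.0, -1.0])
    sheet2 = sheet.reshape(-1, 3) @ flip.T
    sheet2 = sheet2.reshape(N_STRANDS, N_RESIDUES, 4, 3)
    sheet2 = sheet2 + np.array([0.0, (N_STRANDS - 1) * strand_spacing, sheet_separation])
    return Scaffold(np.stack([sheet, sheet2]), sequence=sequence)


@dataclass
class ZipperTemplate:
    """One rigid-body pose of the second sheet against the first.

    ``shift`` (A) translates sheet 2 along the chain axis; ``separation``
    (A) fixes the sheet-normal centroid distance. Sheet 1 never moves.
    """

    shift: float
    separation: float
    coords: np.ndarray  # same layout as Scaffold.coords
    scaffold_sequence: str

    @property
    def name(self) -> str:
        return f"shift{int(self.shift)}_sep{int(self.separation)}"


def enumerate_templates(
    scaffold: Scaffold,
    shifts: Iterable[float] = DEFAULT_SHIFTS,
    separations: Iterable[float] = DEFAULT_SEPARATIONS,
) -> list[ZipperTemplate]:
    """One template per (shift, separation) grid point, sorted by grid.

    The default 9 x 6 grid yields 54 templates. Each template translates
    the canonical second sheet by ``shift`` along the chain axis and by
    ``separation - native_separation`` along the sheet normal, leaving
    every intra-sheet distance untouched (rigid body).
    """
    axis = scaffold.chain_axis()
    normal = scaffold.sheet_normal()
    native = scaffold.sheet_separation()
    templates = []
    for shift in sorted(shifts):
        for sep in sorted(separations):
            coords = scaffold.coords.copy()
            coords[1] += shift * axis + (sep - native) * normal
            templates.append(
                ZipperTemplate(
                    shift=float(shift),
                    separation=float(sep),
                    coords=coords,
                    scaffold_sequence=scaffold.sequence,
                )
            )
    return templates


@dataclass
class ThreadedStructure:
    """A hexapeptide threaded on all 10 chains of a template backbone.

    Residue identities come from the peptide; side-chain placement is the
    energy adapter's job. Chains A-E form sheet 1, F-J sheet 2.
    """

    template: ZipperTemplate
    peptide: str
    chain_ids: tuple[str, ...] = tuple(CHAIN_IDS)

    def chain_sequences(self) -> dict[str, str]:
        return {cid: self.peptide for cid in self.chain_ids}


def thread_peptide(template: ZipperTemplate, peptide: str) -> ThreadedStructure:
    """Assign the peptide's residues to every chain of the template.

    The peptide must be sanitized: cysteines would form disulfide bridges
    between the tightly packed chains, so they are rejected here.
    """
    validate_hexapeptide(peptide)  # rejects cysteine
    if template.coords.shape[2] != len(peptide):
        raise ValueError("peptide length does not match template residues")
    return ThreadedStructure(template=template, peptide=peptide)


#: Contract for external energy computation: (peptide, template) -> one
#: energy per chain, in kcal/mol, 10 values for the 2x5-chain zipper.
EnergyAdapter = Callable[[str, ZipperTemplate], Sequence[float]]


@dataclass(frozen=True)
class MinEnergyResult:
    min_energy: float
    label: bool
    template: ZipperTemplate
    n_failures: int = 0


def min_energy_label(
    peptide: str,
    templates: Sequence[ZipperTemplate],
    adapter: EnergyAdapter,
    threshold: float = -23.0,
) -> MinEnergyResult:
    """Minimal per-chain energy over all templates; label against threshold.

    A peptide is amyloidogenic iff at least one chain of its best template
    reaches an energy not greater than the threshold. Adapter failures on
    individual templates are skipped and counted; if every template
    fails, an error is raised.
    """
    if not templates:
        raise ValueError("no templates supplied")
    best: float | None = None
    best_template: ZipperTemplate | None = None
    failures = 0
    for tpl in templates:
        try:
            energies = list(adapter(peptide, tpl))
        except Exception as exc:  # adapter boundary: skip, count, log
            failures += 1
            logger.warning("adapter failed on %s: %s", tpl.name, exc)
            continue
        if len(energies) != 2 * N_STRANDS:
            raise ValueError(f"adapter must return 10 chain energies, got {len(energies)}")
        low = min(float(e) for e in energies)
        if best is None or low < best:
            best = low
            best_template = tpl
    if best is None:
        raise RuntimeError("energy adapter failed on every template")
    return MinEnergyResult(
        min_energy=best, label=best <= threshold, template=best_template, n_failures=failures
    )


class HydropathySurrogateAdapter:
    """Deterministic toy energy — NOT a physical model.

    Exists so the threading/minimum-selection machinery can be exercised
    end to end without an external design program. Each chain's energy is
    an affine function of the peptide's summed Kyte-Doolittle hydropathy,
    a quadratic penalty of the separation away from a preferred value,
    and a shift penalty; a small per-chain offset makes per-chain minima
    distinguishable.
    """

    def __init__(
        self,
        preferred_separation: float = 8.0,
        hydropathy_weight: float = 1.5,
        offset: float = -18.0,
    ):
        self.preferred_separation = preferred_separation
        self.hydropathy_weight = hydropathy_weight
        self.offset = offset

    def __call__(self, peptide: str, template: ZipperTemplate) -> list[float]:
        hydro = sum(KYTE_DOOLITTLE[aa] for aa in peptide)
        base = (
            self.offset
            - self.hydropathy_weight * hydro
            + 0.8 * (template.separation - self.preferred_separation) ** 2
            + 0.3 * template.shift
        )
        return [base + 0.05 * chain for chain in range(2 * N_STRANDS)]


# ---------------------------------------------------------------------------
# PDB interchange (Biopython)


def _build_structure(coords: np.ndarray, chain_sequences: dict[str, str]):
    builder = StructureBuilder()
    builder.init_structure("zipper")
    builder.init_model(0)
    flat = coords.reshape(2 * N_STRANDS, coords.shape[2], 4, 3)
    for chain_idx, cid in enumerate(CHAIN_IDS):
        builder.init_chain(cid)
        builder.init_seg("    ")
        seq = chain_sequences[cid]
        for r in range(flat.shape[1]):
            builder.init_residue(AA_THREE[seq[r]], " ", r + 1, " ")
            for a, atom_name in enumerate(BACKBONE_ATOMS):
                builder.init_atom(
                    atom_name,
                    flat[chain_idx, r, a],
                    0.0,
                    1.0,
                    " ",
                    f" {atom_name:<3s}"[:4],
                    element=atom_name[0],
                )
    return builder.get_structure()


def write_pdb(path, obj: ZipperTemplate | ThreadedStructure) -> None:
    """Write a template (scaffold sequence) or threaded structure as PDB."""
    if isinstance(obj, ThreadedStructure):
        coords = obj.template.coords
        seqs = obj.chain_sequences()
    else:
        coords = obj.coords
        seqs = {cid: obj.scaffold_sequence for cid in CHAIN_IDS}
    io = PDBIO()
    io.set_structure(_build_structure(coords, seqs))
    io.save(str(path))


def read_scaffold_pdb(
    path,
    sheet1_chains: Sequence[str] = CHAIN_IDS[:N_STRANDS],
    sheet2_chains: Sequence[str] = CHAIN_IDS[N_STRANDS:],
) -> Scaffold:
    """Read backbone coordinates of a two-sheet scaffold from a PDB file.

    The caller names which chains form each sheet; every chain must carry
    the same number of residues with N, CA, C, O atoms present.
    """
    structure = PDBParser(QUIET=True).get_structure("scaffold", str(path))
    model = next(iter(structure))
    chains = {ch.id: ch for ch in model}
    sheets = []
    sequence = None
    for chain_ids in (sheet1_chains, sheet2_chains):
        strands = []
        for cid in chain_ids:
            if cid not in chains:
                raise ValueError(f"chain {cid!r} missing from {path}")
            residues = [res for res in chains[cid] if res.id[0] == " "]
            strand = np.array(
                [[res[a].coord for a in BACKBONE_ATOMS] for res in residues]
            )
            strands.append(strand)
            three_to_one = {v: k for k, v in AA_THREE.items()}
            seq = "".join(three_to_one.get(res.get_resname(), "X") for res in residues)
            sequence = sequence or seq
        sheets.append(np.array(strands))
    return Scaffold(np.stack(sheets), sequence=sequence)
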