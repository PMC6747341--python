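"""Structures, trajectories, parameter tables, domain definitions and atom selection.

The static side of every computation is a :class:`MolecularSystem` (atoms with
nonbonded parameters and domain labels); the dynamic side is a
:class:`Trajectory` (frames x atoms x 3, nm, with periodic box vectors).
File formats (PDB, XTC, DCD) are read and written through mdtraj.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

try:  # tomllib is stdlib from 3.11
    import tomllib
except ImportError:  # pragma: no cover
    tomllib = None

import yaml

from .constants import ION_CHARGE, ION_LJ

#: Residue names treated as monoatomic ions / solvent when labelling domains.
ION_RESNAMES = {"ZN", "CA", "MG", "NA", "CL", "K", "ZN2", "CA2"}
SOLVENT_RESNAMES = {"HOH", "SOL", "TIP3", "TIP3P", "WAT", "SPC"}

DOMAIN_LABELS = ("Cat", "Fib", "Hpx", "Lnk", "ion", "solvent", "other")

_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "ZN": 65.38, "CA": 40.078, "NA": 22.990, "CL": 35.45,
    "MG": 24.305, "K": 39.098, "FE": 55.845, "X": 12.011,
}


def _element_from_name(name: str, resname: str) -> str:
    """Guess an element symbol from a PDB atom name (fallback path only)."""
    if resname.strip().upper() in ION_RESNAMES:
        return resname.strip().upper()[:2].capitalize()
    stripped = name.strip()
    if stripped[:2].upper() in ("CL", "BR", "NA", "MG", "ZN", "FE") and len(stripped) <= 2:
        return stripped.capitalize()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "C"


# ---------------------------------------------------------------------------
# Domain configuration
# ---------------------------------------------------------------------------

@dataclass
class DomainConfig:
    """Named residue ranges (1-based author numbering, inclusive) per domain.

    ``domains`` maps a label to a list of ``(start, end)`` ranges. Ranges of
    different labels may nest (the fibronectin insert sits inside the catalytic
    domain); labels listed earlier take precedence when assigning a residue.
    """

    domains: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    ion_names: list[str] = field(default_factory=lambda: sorted(ION_RESNAMES))
    equilibration_ns: float = 200.0
    stride_ns: float = 0.1

    def __post_init__(self) -> None:
        if self.equilibration_ns < 0:
            raise ValueError("equilibration cutoff must be >= 0")
        for label, ranges in self.domains.items():
            for lo, hi in ranges:
                if lo > hi:
                    raise ValueError(f"empty range {lo}-{hi} for domain {label!r}")

    def label_for_residue(self, resid: int) -> str:
        for label, ranges in self.domains.items():
            for lo, hi in ranges:
                if lo <= resid <= hi:
                    return label
        return "other"

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "DomainConfig":
        path = Path(path)
        if path.suffix in (".toml", ".tml"):
            if tomllib is None:  # pragma: no cover
                raise RuntimeError("tomllib unavailable")
            data = tomllib.loads(path.read_text())
        else:
            data = yaml.safe_load(path.read_text())
        domains = {
            label: [tuple(r) for r in ranges]
            for label, ranges in data.get("domains", {}).items()
        }
        return cls(
            domains=domains,
            ion_names=list(data.get("ion_names", sorted(ION_RESNAMES))),
            equilibration_ns=float(data.get("equilibration_ns", 200.0)),
            stride_ns=float(data.get("stride_ns", 0.1)),
        )


def mmp2_domain_config() -> DomainConfig:
    """Default MMP-2 domain definition.

    Fib (217-393) is inserted within Cat (110-445); Fib is listed first so the
    plain ``Cat`` label means "Cat without Fib".  The union is available as the
    selection ``domain Cat or domain Fib``.
    """
    return DomainConfig(
        domains={
            "Fib": [(217, 393)],
            "Cat": [(110, 445)],
            "Lnk": [(446, 460)],
            "Hpx": [(461, 660)],
        }
    )


# ---------------------------------------------------------------------------
# Parameter table
# ---------------------------------------------------------------------------

@dataclass
class ParameterTable:
    """Nonbonded lookup: (resname, atomname) -> (q, sigma, epsilon).

    Plain-text TSV columns: resname, atomname, charge (e), sigma (nm),
    epsilon (kJ/mol).  ``*`` wildcards the residue name; rows with resname
    ``ELEM`` match by element symbol as a last resort.
    """

    exact: dict[tuple[str, str], tuple[float, float, float]] = field(default_factory=dict)
    by_name: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    by_element: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "ParameterTable":
        table = cls()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            res, name, q, sig, eps = line.split()[:5]
            entry = (float(q), float(sig), float(eps))
            if res == "ELEM":
                table.by_element[name.upper()] = entry
            elif res == "*":
                table.by_name[name.upper()] = entry
            else:
                table.exact[(res.upper(), name.upper())] = entry
        return table

    def lookup(self, resname: str, atomname: str, element: str):
        resname, atomname = resname.upper(), atomname.upper()
        # His protonation variants are aliased to HIS at lookup.
        if resname in ("HSD", "HSE", "HSP", "HID", "HIE"):
            resname = "HIS"
        for key in ((resname, atomname),):
            if key in self.exact:
                return self.exact[key]
        if atomname in self.by_name:
            return self.by_name[atomname]
        if element.upper() in self.by_element:
            return self.by_element[element.upper()]
        return None


def default_parameter_table() -> ParameterTable:
    """Minimal shipped table: ions, water oxygen and element fallbacks."""
    return ParameterTable.from_file(
        Path(__file__).parent / "data" / "default_params.tsv"
    )


# ---------------------------------------------------------------------------
# MolecularSystem / Trajectory
# ---------------------------------------------------------------------------

@dataclass
class MolecularSystem:
    """Atoms, residues, chains, nonbonded parameters and domain labels."""

    names: np.ndarray
    elements: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    chains: np.ndarray
    charges: np.ndarray
    sigmas: np.ndarray
    epsilons: np.ndarray
    masses: np.ndarray
    domains: np.ndarray
    domain_config: DomainConfig | None = None

    def __post_init__(self) -> None:
        n = len(self.names)
        for arr_name in ("elements", "resids", "resnames", "chains", "charges",
                         "sigmas", "epsilons", "masses", "domains"):
            if len(getattr(self, arr_name)) != n:
                raise ValueError(f"field {arr_name} length mismatch")
        if np.any(self.sigmas < 0) or np.any(self.epsilons < 0):
            raise ValueError("sigma and epsilon must be non-negative")
        if not np.all(np.isfinite(self.charges)):
            raise ValueError("charges must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def atom_residue(self, i: int) -> tuple[int, str]:
        return int(self.resids[i]), str(self.resnames[i])

    def to_mdtraj_topology(self):
        """Build an mdtraj Topology mirroring atom/residue/chain structure."""
        import mdtraj as md
        from mdtraj.core import element as melem

        top = md.Topology()
        chain_map: dict[str, object] = {}
        res_key = None
        res = None
        for i in range(self.n_atoms):
            cid = str(self.chains[i])
            if cid not in chain_map:
                chain_map[cid] = top.add_chain()
            key = (cid, int(self.resids[i]), str(self.resnames[i]))
            if key != res_key:
                res = top.add_residue(str(self.resnames[i]), chain_map[cid],
                                      resSeq=int(self.resids[i]))
                res_key = key
            sym = str(self.elements[i]).capitalize()
            try:
                el = melem.get_by_symbol(sym)
            except KeyError:
                el = melem.carbon
            top.add_atom(str(self.names[i]), el, res)
        return top


@dataclass
class Trajectory:
    """Frames x atoms x 3 coordinates (nm), times (ns), per-frame box vectors (nm)."""

    coords: np.ndarray
    times: np.ndarray
    box: np.ndarray | None = None  # (n_frames, 3, 3) triclinic vectors

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if len(self.times) != self.coords.shape[0]:
            raise ValueError("times length != n_frames")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (self.n_frames, 3, 3):
                raise ValueError("box must have shape (n_frames, 3, 3)")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def slice_frames(self, mask_or_idx) -> "Trajectory":
        idx = np.asarray(mask_or_idx)
        return Trajectory(
            self.coords[idx],
            self.times[idx],
            None if self.box is None else self.box[idx],
        )

    def after(self, t_ns: float) -> "Trajectory":
        """Frames with time >= t_ns (the equilibrated analysis window)."""
        return self.slice_frames(self.times >= t_ns)


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

class ParameterLookupError(ValueError):
    """An atom had no parameters and no documented fallback applied."""


def load_system(
    structure_file: str | os.PathLike,
    parameter_table: str | os.PathLike | ParameterTable | None = None,
    domain_config: str | os.PathLike | DomainConfig | None = None,
    strict: bool = True,
) -> tuple[MolecularSystem, Trajectory]:
    """Read a PDB structure and populate a fully parameterised system.

    Returns the system together with the (single- or multi-frame) coordinates
    found in the file.  Atoms whose (resname, name) resolve neither exactly nor
    via wildcard/element fallback raise :class:`ParameterLookupError` listing
    them, unless ``strict=False`` (they then get q=0, sigma=eps=0).
    """
    import mdtraj as md

    path = Path(structure_file)
    if not path.exists():
        raise FileNotFoundError(path)
    t = md.load(str(path))

    if parameter_table is None:
        table = default_parameter_table()
    elif isinstance(parameter_table, ParameterTable):
        table = parameter_table
    else:
        table = ParameterTable.from_file(parameter_table)

    if domain_config is None:
        dconf = mmp2_domain_config()
    elif isinstance(domain_config, DomainConfig):
        dconf = domain_config
    else:
        dconf = DomainConfig.from_file(domain_config)

    n = t.n_atoms
    names = np.empty(n, dtype=object)
    elements = np.empty(n, dtype=object)
    resids = np.empty(n, dtype=int)
    resnames = np.empty(n, dtype=object)
    chains = np.empty(n, dtype=object)
    charges = np.zeros(n)
    sigmas = np.zeros(n)
    epsilons = np.zeros(n)
    masses = np.zeros(n)
    domains = np.empty(n, dtype=object)
    unresolved: list[str] = []

    for i, atom in enumerate(t.topology.atoms):
        res = atom.residue
        names[i] = atom.name
        sym = atom.element.symbol if atom.element is not None else \
            _element_from_name(atom.name, res.name)
        elements[i] = sym.upper() if len(sym) <= 2 else sym[:2].upper()
        resids[i] = res.resSeq
        resnames[i] = res.name
        chains[i] = str(res.chain.index)
        masses[i] = atom.element.mass if atom.element is not None else \
            _MASSES.get(elements[i], 12.011)
        rn = res.name.upper()
        if rn in SOLVENT_RESNAMES:
            domains[i] = "solvent"
        elif rn in set(x.upper() for x in dconf.ion_names) and res.n_atoms == 1:
            domains[i] = "ion"
        else:
            domains[i] = dconf.label_for_residue(int(res.resSeq))
        entry = table.lookup(res.name, atom.name, str(elements[i]))
        if domains[i] == "ion":
            # Formal charge and CM-model LJ for the supported ions.
            key = rn[:2]
            charges[i] = ION_CHARGE.get(key, 0.0)
            sigmas[i], epsilons[i] = ION_LJ.get(key, (0.0, 0.0))
            if entry is not None:
                charges[i], sigmas[i], epsilons[i] = entry
        elif entry is not None:
            charges[i], sigmas[i], epsilons[i] = entry
        else:
            unresolved.append(f"{res.name}{res.resSeq}:{atom.name}")

    if unresolved and strict:
        raise ParameterLookupError(
            "no parameters for atoms: " + ", ".join(unresolved[:20])
            + ("..." if len(unresolved) > 20 else "")
        )

    system = MolecularSystem(
        names=names, elements=elements, resids=resids, resnames=resnames,
        chains=chains, charges=charges, sigmas=sigmas, epsilons=epsilons,
        masses=masses, domains=domains, domain_config=dconf,
    )
    times = np.asarray(t.time, dtype=float) / 1000.0  # ps -> ns
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        times = np.arange(t.n_frames, dtype=float)
    box = t.unitcell_vectors
    traj = Trajectory(np.asarray(t.xyz, dtype=float), times, box)
    return system, traj


def load_trajectory(
    traj_file: str | os.PathLike,
    system: MolecularSystem,
) -> Trajectory:
    """Read a multi-model PDB, XTC or DCD trajectory against ``system``."""
    import mdtraj as md

    path = Path(traj_file)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".pdb":
        t = md.load(str(path))
    elif suffix in (".xtc", ".dcd"):
        try:
            t = md.load(str(path), top=system.to_mdtraj_topology())
        except Exception as exc:
            raise ValueError(
                f"atom-count mismatch or unreadable trajectory {path}: {exc}"
            ) from exc
    else:
        raise ValueError(f"unsupported trajectory format: {suffix}")
    if t.n_atoms != system.n_atoms:
        raise ValueError(
            f"atom-count mismatch: trajectory has {t.n_atoms}, system {system.n_atoms}"
        )
    times = np.asarray(t.time, dtype=float) / 1000.0
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        times = np.arange(t.n_frames, dtype=float)
    return Trajectory(np.asarray(t.xyz, dtype=float), times, t.unitcell_vectors)


def write_trajectory(
    traj: Trajectory,
    system: MolecularSystem,
    path: str | os.PathLike,
) -> None:
    """Write frames as PDB / XTC / DCD (format from the file extension)."""
    import mdtraj as md

    t = md.Trajectory(
        xyz=np.asarray(traj.coords, dtype=np.float32),
        topology=system.to_mdtraj_topology(),
        time=np.asarray(traj.times, dtype=float) * 1000.0,
    )
    if traj.box is not None:
        t.unitcell_vectors = np.asarray(traj.box, dtype=np.float32)
    t.save(str(path))


def write_pdb_frame(
    traj: Trajectory, system: MolecularSystem, frame: int, path: str | os.PathLike
) -> None:
    write_trajectory(traj.slice_frames([frame]), system, path)


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

def select(system: MolecularSystem, expression: str) -> np.ndarray:
    """Evaluate a selection expression, returning sorted atom indices.

    Grammar (whitespace-separated, case-sensitive values)::

        expr     := term (" or " term)*
        term     := factor (" and " factor)*
        factor   := ["not "] primary
        primary  := "all"
                  | "name" V+ | "resname" V+ | "element" V+ | "chain" V+
                  | "domain" V+ | "resid" N | "resid" N "to" N

    Examples: ``"name CA and domain Cat"``, ``"resid 110 to 445"``.
    """
    n = system.n_atoms

    def primary(tokens: list[str]) -> np.ndarray:
        key = tokens.pop(0)
        if key == "all":
            return np.ones(n, dtype=bool)
        if key == "resid":
            if not tokens:
                raise ValueError("resid requires arguments")
            lo = int(tokens.pop(0))
            if len(tokens) >= 2 and tokens[0] == "to":
                tokens.pop(0)
                hi = int(tokens.pop(0))
            else:
                hi = lo
                vals = {lo}
                while tokens and tokens[0].lstrip("-").isdigit():
                    vals.add(int(tokens.pop(0)))
                return np.isin(system.resids, sorted(vals))
            return (system.resids >= lo) & (system.resids <= hi)
        fields = {
            "name": system.names, "resname": system.resnames,
            "element": system.elements, "chain": system.chains,
            "domain": system.domains,
        }
        if key not in fields:
            raise ValueError(f"malformed selection near {key!r}")
        vals = []
        while tokens and tokens[0] not in ("and", "or", "not", "to"):
            vals.append(tokens.pop(0))
        if not vals:
            raise ValueError(f"{key} requires at least one value")
        arr = fields[key]
        if key == "element":
            vals = [v.upper() for v in vals]
            return np.isin(np.char.upper(arr.astype(str)), vals)
        return np.isin(arr.astype(str), vals)

    def factor(tokens: list[str]) -> np.ndarray:
        if tokens and tokens[0] == "not":
            tokens.pop(0)
            return ~factor(tokens)
        return primary(tokens)

    def term(tokens: list[str]) -> np.ndarray:
        mask = factor(tokens)
        while tokens and tokens[0] == "and":
            tokens.pop(0)
            mask = mask & factor(tokens)
        return mask

    tokens = expression.split()
    if not tokens:
        raise ValueError("empty selection expression")
    mask = term(tokens)
    while tokens and tokens[0] == "or":
        tokens.pop(0)
        mask = mask | term(tokens)
    if tokens:
        raise ValueError(f"malformed selection: trailing tokens {tokens!r}")
    return np.flatnonzero(mask)
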