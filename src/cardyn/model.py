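"""Core data model: atoms, frames, trajectories, domain maps, motif scans.

Everything downstream operates on :class:`Trajectory` (topology shared by
all frames, coordinates as one ``(n_frames, n_atoms, 3)`` array in Å) and a
:class:`DomainMap` that names the receptor domains (AB antigen-binding, HI
hinge, TM transmembrane, CS costimulatory, SI signaling, optionally AG for
the bound antigen) plus residue groups such as the CD3ζ polybasic regions
and ITAMs. Residue numbering is author numbering from the PDB, 1-based,
with inclusive ranges; hydrogens are parsed but excluded from analyses by
default.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import yaml

from .errors import ConfigError, FormatError, SelectionError

RECEPTOR_DOMAINS = ("AB", "HI", "TM", "CS", "SI")
OPTIONAL_DOMAINS = ("AG",)
KNOWN_GROUPS = ("PBR1", "PBR2", "PBR3", "ITAM1", "ITAM2", "ITAM3", "ITAM_TYR")

#: CD3ζ polybasic regions in construct numbering (inclusive ranges).
DEFAULT_PBR_RANGES = {"PBR1": (395, 399), "PBR2": (406, 410), "PBR3": (435, 442)}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the shared topology."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str
    position: np.ndarray  # (3,) Å
    is_hetero: bool = False

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


class Frame:
    """A single trajectory frame: the shared topology plus one coordinate set."""

    def __init__(self, topology: Sequence[AtomRecord], coords: np.ndarray, index: int = 0):
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(topology), 3):
            raise FormatError(
                f"frame {index}: coordinate shape {coords.shape} does not match "
                f"topology of {len(topology)} atoms"
            )
        if not np.all(np.isfinite(coords)):
            raise FormatError(f"frame {index}: non-finite coordinates")
        self.topology = list(topology)
        self.coords = coords
        self.index = index

    @property
    def atoms(self) -> list[AtomRecord]:
        """Atom records with this frame's positions filled in."""
        return [
            AtomRecord(a.serial, a.name, a.element, a.residue_name, a.residue_id,
                       a.chain_id, self.coords[i].copy(), a.is_hetero)
            for i, a in enumerate(self.topology)
        ]

    def __len__(self) -> int:
        return len(self.topology)


class Trajectory:
    """An ordered sequence of frames over one topology.

    Coordinates are stored as a single ``(n_frames, n_atoms, 3)`` float array
    so per-frame geometry loops stay vectorised.
    """

    def __init__(self, topology: Sequence[AtomRecord], coords: np.ndarray,
                 time_per_frame: float | None = None):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[0] < 1 or coords.shape[1:] != (len(topology), 3):
            raise FormatError(
                f"trajectory coordinates must have shape (n_frames, {len(topology)}, 3); "
                f"got {coords.shape}"
            )
        self.topology = list(topology)
        self.coords = coords
        self.time_per_frame = time_per_frame

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> Frame:
        return Frame(self.topology, self.coords[i], index=i)

    def __iter__(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def __len__(self) -> int:
        return self.n_frames

    @classmethod
    def from_frames(cls, frames: Sequence[Frame],
                    time_per_frame: float | None = None) -> "Trajectory":
        if not frames:
            raise FormatError("trajectory requires at least one frame")
        topo = frames[0].topology
        for f in frames[1:]:
            if len(f.topology) != len(topo):
                raise FormatError(
                    f"frame {f.index}: atom count {len(f.topology)} differs from "
                    f"frame 0 ({len(topo)})"
                )
        return cls(topo, np.stack([f.coords for f in frames]), time_per_frame)


@dataclass(frozen=True)
class AtomSelection:
    """Ordered indices into a trajectory's topology."""

    indices: tuple[int, ...]
    label: str

    def __post_init__(self):
        idx = self.indices
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise SelectionError(f"selection '{self.label}': indices not strictly increasing")

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)


@dataclass(frozen=True)
class MotifHit:
    """An ITAM-pattern match: Yxx(L/I) x{spacer} Yxx(L/I)."""

    start: int  # 1-based position of the first tyrosine
    spacer_length: int
    matched_text: str


# ---------------------------------------------------------------------------
# Multi-model PDB I/O
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        residue_name = line[17:20].strip()
        chain_id = line[21].strip() or "A"
        residue_id = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"line {lineno}: unparsable ATOM/HETATM record: {exc}") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # fall back to the leading letter of the atom name
        element = next((c for c in name if c.isalpha()), "X")
    return AtomRecord(
        serial=serial, name=name, element=element, residue_name=residue_name,
        residue_id=residue_id, chain_id=chain_id,
        position=np.array([x, y, z]), is_hetero=line.startswith("HETATM"),
    )


def read_multimodel_pdb(path: str | Path) -> Trajectory:
    """Read a (possibly multi-model) PDB file into a :class:`Trajectory`.

    MODEL/ENDMDL blocks delimit frames; a file without MODEL records is a
    single frame. HETATM records (membrane/pseudo-atoms) are retained with
    ``is_hetero`` set. All models must present the same atoms in the same
    order.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    model_no = 1
    in_model = False
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                saw_model = True
                in_model = True
                try:
                    model_no = int(line.split()[1])
                except (IndexError, ValueError):
                    model_no = len(models) + 1
                current = []
            elif rec == "ENDMDL":
                models.append(current)
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                current.append(_parse_atom_line(line, lineno))
    if saw_model and in_model:
        models.append(current)  # MODEL without trailing ENDMDL
    if not saw_model:
        models = [current]
    models = [m for m in models if m] or [[]]
    if not models[0]:
        raise FormatError(f"{path}: no ATOM/HETATM records found")

    topo = models[0]
    n = len(topo)
    coords = np.empty((len(models), n, 3))
    for k, model in enumerate(models):
        if len(model) != n:
            raise FormatError(
                f"{path}: MODEL {k + 1} has {len(model)} atoms but MODEL 1 has {n}"
            )
        for i, atom in enumerate(model):
            ref = topo[i]
            if (atom.chain_id, atom.residue_id, atom.name) != (
                    ref.chain_id, ref.residue_id, ref.name):
                raise FormatError(
                    f"{path}: MODEL {k + 1} atom {i + 1} "
                    f"({atom.chain_id}/{atom.residue_id}/{atom.name}) does not match "
                    f"MODEL 1 ({ref.chain_id}/{ref.residue_id}/{ref.name})"
                )
            coords[k, i] = atom.position
    return Trajectory(topo, coords)


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as MODEL/ENDMDL-delimited PDB (%8.3f coordinates)."""
    if np.any(np.abs(traj.coords) >= 10000.0):
        raise FormatError("coordinate magnitude >= 10000 Å overflows PDB fixed columns")
    lines: list[str] = []
    for k in range(traj.n_frames):
        lines.append(f"MODEL     {k + 1:4d}")
        for i, a in enumerate(traj.topology):
            record = "HETATM" if a.is_hetero else "ATOM  "
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            x, y, z = traj.coords[k, i]
            lines.append(
                f"{record}{a.serial % 100000:5d} {name:<4s}{'':1s}{a.residue_name:>3s} "
                f"{a.chain_id:1s}{a.residue_id % 10000:4d}{'':4s}"
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}{'':10s}{a.element:>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Domain map
# ---------------------------------------------------------------------------

@dataclass
class DomainMap:
    """Named residue ranges and groups that drive every selection.

    ``domains`` maps a domain name to inclusive ``(chain_id, start, end)``
    residue ranges; ``groups`` maps a group name (PBR1..3, ITAM1..3,
    ITAM_TYR) to explicit residue-id lists. Membrane atoms are selected as
    HETATM records with the configured lipid residue code.
    """

    domains: dict[str, list[tuple[str, int, int]]]
    groups: dict[str, list[int]] = field(default_factory=dict)
    membrane_residue: str = "POP"
    membrane_slab_halfwidth: float = 15.0

    def __post_init__(self):
        missing = [d for d in RECEPTOR_DOMAINS if d not in self.domains]
        if missing:
            raise ConfigError(f"domain map missing required domain(s): {', '.join(missing)}")
        self._check_overlaps()
        self._fill_default_pbrs()

    def _check_overlaps(self) -> None:
        spans: list[tuple[str, str, int, int]] = []
        for name, ranges in self.domains.items():
            for chain, lo, hi in ranges:
                if lo > hi:
                    raise ConfigError(f"domain {name}: range {lo}-{hi} has start > end")
                spans.append((name, chain, lo, hi))
        for i, (n1, c1, a1, b1) in enumerate(spans):
            for n2, c2, a2, b2 in spans[i + 1:]:
                if n1 != n2 and c1 == c2 and a1 <= b2 and a2 <= b1:
                    raise ConfigError(
                        f"overlapping domain ranges: {n1} {c1}:{a1}-{b1} "
                        f"collides with {n2} {c2}:{a2}-{b2}"
                    )

    def _fill_default_pbrs(self) -> None:
        covered = set()
        for ranges in self.domains.values():
            for _, lo, hi in ranges:
                covered.update(range(lo, hi + 1))
        for name, (lo, hi) in DEFAULT_PBR_RANGES.items():
            if name not in self.groups and covered.issuperset(range(lo, hi + 1)):
                self.groups[name] = list(range(lo, hi + 1))

    def membrane_selection(self, atom: AtomRecord) -> bool:
        return atom.is_hetero and atom.residue_name == self.membrane_residue

    def resolve(self, spec: str) -> list[tuple[str | None, int, int]]:
        """Resolve a domain or group name into (chain, start, end) ranges."""
        if spec in self.domains:
            return [(c, lo, hi) for c, lo, hi in self.domains[spec]]
        if spec in self.groups:
            return [(None, r, r) for r in self.groups[spec]]
        raise SelectionError(
            f"unknown domain or group '{spec}' "
            f"(domains: {sorted(self.domains)}; groups: {sorted(self.groups)})"
        )


_DOMAIN_MAP_KEYS = {"domains", "groups", "membrane_residue", "membrane_slab_halfwidth"}


def load_domain_map(path: str | Path) -> DomainMap:
    """Load and validate a YAML domain-map configuration.

    Schema::

        domains:
          AB: [[A, 1, 250]]      # chain, first residue, last residue
          HI: [[A, 251, 295]]
          ...
        groups:                   # optional; PBRs default to 395-399,
          ITAM1: [...]            # 406-410, 435-442 when covered
        membrane_residue: POP
        membrane_slab_halfwidth: 15.0

    Unknown keys are rejected so a typo cannot silently change a run.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"domain map not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: domain map must be a mapping")
    unknown = set(raw) - _DOMAIN_MAP_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown key(s): {', '.join(sorted(unknown))}")
    if "domains" not in raw:
        raise ConfigError(f"{path}: missing 'domains' section")
    domains: dict[str, list[tuple[str, int, int]]] = {}
    for name, ranges in raw["domains"].items():
        if name not in RECEPTOR_DOMAINS + OPTIONAL_DOMAINS:
            raise ConfigError(f"{path}: unknown domain '{name}'")
        if ranges and not isinstance(ranges[0], (list, tuple)):
            ranges = [ranges]
        parsed = []
        for r in ranges:
            if len(r) == 3:
                chain, lo, hi = r
            elif len(r) == 2:
                chain, (lo, hi) = "A", r
            else:
                raise ConfigError(f"{path}: domain {name}: bad range {r!r}")
            parsed.append((str(chain), int(lo), int(hi)))
        domains[name] = parsed
    groups: dict[str, list[int]] = {}
    for name, residues in (raw.get("groups") or {}).items():
        if name not in KNOWN_GROUPS:
            raise ConfigError(f"{path}: unknown group '{name}'")
        groups[name] = [int(r) for r in residues]
    return DomainMap(
        domains=domains,
        groups=groups,
        membrane_residue=str(raw.get("membrane_residue", "POP")),
        membrane_slab_halfwidth=float(raw.get("membrane_slab_halfwidth", 15.0)),
    )


def write_domain_map(dmap: DomainMap, path: str | Path) -> None:
    """Serialise a DomainMap back to its YAML schema."""
    data = {
        "domains": {k: [list(r) for r in v] for k, v in dmap.domains.items()},
        "groups": {k: list(v) for k, v in dmap.groups.items()},
        "membrane_residue": dmap.membrane_residue,
        "membrane_slab_halfwidth": dmap.membrane_slab_halfwidth,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


# ---------------------------------------------------------------------------
# Atom selection
# ---------------------------------------------------------------------------

def select_atoms(traj: Trajectory, dmap: DomainMap,
                 spec: str | Iterable[tuple[str | None, int, int]],
                 atom_name: str | None = None,
                 include_hydrogens: bool = False) -> AtomSelection:
    """Select topology indices by domain name, group name, or residue ranges.

    Ordering follows the topology; an empty result raises rather than
    returning silently. Hydrogens are excluded unless requested.
    """
    if isinstance(spec, str):
        ranges = dmap.resolve(spec)
        label = spec
    else:
        ranges = [(c, int(lo), int(hi)) for c, lo, hi in spec]
        label = ",".join(f"{c or '*'}:{lo}-{hi}" for c, lo, hi in ranges)
    if atom_name:
        label += f"/{atom_name}"
    idx = []
    for i, a in enumerate(traj.topology):
        if atom_name is not None and a.name != atom_name:
            continue
        if not include_hydrogens and a.is_hydrogen:
            continue
        for chain, lo, hi in ranges:
            if (chain is None or a.chain_id == chain) and lo <= a.residue_id <= hi:
                idx.append(i)
                break
    if not idx:
        raise SelectionError(f"selection '{label}' matched no atoms")
    return AtomSelection(tuple(idx), label)


def select_membrane(traj: Trajectory, dmap: DomainMap,
                    include_hydrogens: bool = False) -> AtomSelection:
    """All membrane atoms (HETATM with the configured lipid residue code)."""
    idx = [
        i for i, a in enumerate(traj.topology)
        if dmap.membrane_selection(a) and (include_hydrogens or not a.is_hydrogen)
    ]
    if not idx:
        raise SelectionError(
            f"no membrane atoms found (HETATM residue '{dmap.membrane_residue}')"
        )
    return AtomSelection(tuple(idx), "membrane")


# ---------------------------------------------------------------------------
# ITAM motif scanning
# ---------------------------------------------------------------------------

_AA = set("ACDEFGHIKLMNPQRSTVWY")


def scan_itam_motifs(sequence: str, spacer_min: int = 6,
                     spacer_max: int = 12) -> list[MotifHit]:
    """Scan a 1-letter sequence for the ITAM pattern Yxx(L/I) x{n} Yxx(L/I).

    The spacer length n ranges over [spacer_min, spacer_max]; the default
    6-12 spans both conventions in circulation for CD3ζ. Overlapping hits
    are all reported, sorted by start position (1-based) then spacer.
    """
    if spacer_min > spacer_max:
        raise ConfigError(f"spacer_min ({spacer_min}) > spacer_max ({spacer_max})")
    if spacer_min < 0:
        raise ConfigError("spacer_min must be non-negative")
    sequence = sequence.upper()
    bad = set(sequence) - _AA
    if bad:
        raise ConfigError(f"sequence contains non-amino-acid letters: {sorted(bad)}")
    hits: list[MotifHit] = []
    for spacer in range(spacer_min, spacer_max + 1):
        pat = re.compile(rf"(?=(Y..[LI].{{{spacer}}}Y..[LI]))")
        for m in pat.finditer(sequence):
            hits.append(MotifHit(start=m.start() + 1, spacer_length=spacer,
                                 matched_text=m.group(1)))
    hits.sort(key=lambda h: (h.start, h.spacer_length))
    return hits
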