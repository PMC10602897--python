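"""Duplex k-mer enumeration and idealized B-form geometry construction.

A duplex *k*-mer here is a fragment of ``k`` stacked Watson-Crick base pairs
(base pair, dimer, trimer, tetramer) of either a DNA:DNA target duplex or the
DNA:RNA guide:target hybrid.  The module enumerates all non-chimeric strand-1
sequences, builds canonical 3-D coordinates for them (flat idealized
nucleobases, pairs stacked ``rise`` Angstrom apart along z and twisted
``twist`` degrees about the helix axis), and writes the structures as XYZ or
PDB text for consumption by external quantum-chemistry engines.

Geometry conventions
--------------------
* Each base pair is a planar frame: centroid at the origin, base plane in the
  xy-plane, and the pyrimidine C2->O2 carbonyl bond pointing along +x (the
  final in-plane rotation that makes the canonical form unique).
* Base-pair ``i`` of a k-mer is the canonical frame rotated by
  ``(i-1) * twist`` degrees about +z (right-handed) and translated
  ``(i-1) * rise`` Angstrom along +z.
* Bases are idealized flat heterocycles (regular-polygon rings, standard-table
  bond lengths), not crystallographic coordinates: the builder's contract is
  geometric, and no quantum calculation is run here.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Iterable, Sequence

import numpy as np

# --------------------------------------------------------------------------
# constants
# --------------------------------------------------------------------------

DNA_DNA = "DNA:DNA"
DNA_RNA = "DNA:RNA"
DUPLEX_CLASSES = (DNA_DNA, DNA_RNA)

DNA_ALPHABET = ("A", "C", "G", "T")
RNA_ALPHABET = ("A", "C", "G", "U")
#: the joint nucleobase alphabet of both nucleic-acid types
DNA_RNA_ALPHABET = ("A", "C", "G", "T", "U")

#: Watson-Crick partner of a strand-1 (DNA) base, per duplex class.
COMPLEMENT = {
    DNA_DNA: {"A": "T", "T": "A", "G": "C", "C": "G"},
    DNA_RNA: {"A": "U", "T": "A", "G": "C", "C": "G"},
}

DEFAULT_RISE = 3.5  # Angstrom between stacked base-pair centroids
DEFAULT_TWIST = 36.0  # degrees of helical twist per step
MAX_K = 4
#: long-range interaction cut-off: 4 base pairs ~ 14 Angstrom
INTERACTION_CUTOFF = 14.0

PYRIMIDINES = frozenset("CTU")
PURINES = frozenset("AG")

CANONICAL_TOL = 1e-6


class DuplexError(ValueError):
    """Base class for duplex-construction failures."""


class KmerRangeError(DuplexError):
    """k outside the supported 1..4 range."""


class TemplateError(DuplexError):
    """Missing or unresolvable base template / atom labels."""


# --------------------------------------------------------------------------
# idealized base templates
# --------------------------------------------------------------------------

_RING_SIDE = 1.39  # aromatic C-C/C-N bond, Angstrom
_BOND_CO = 1.23  # carbonyl C=O
_BOND_CN = 1.34  # exocyclic C-N (amine)
_BOND_CC = 1.50  # exocyclic C-C (thymine methyl)

# exocyclic substituents: base -> list of (parent ring atom, label, bond length)
_EXOCYCLIC = {
    "A": [("C6", "N6", _BOND_CN)],
    "G": [("C6", "O6", _BOND_CO), ("C2", "N2", _BOND_CN)],
    "C": [("C2", "O2", _BOND_CO), ("C4", "N4", _BOND_CN)],
    "T": [("C2", "O2", _BOND_CO), ("C4", "O4", _BOND_CO), ("C5", "C7", _BOND_CC)],
    "U": [("C2", "O2", _BOND_CO), ("C4", "O4", _BOND_CO)],
}

_PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")


def _hexagon_ring() -> dict[str, np.ndarray]:
    """Six-membered ring vertices (regular hexagon, side 1.39 A), xy-plane."""
    radius = _RING_SIDE  # circumradius of a regular hexagon equals its side
    out = {}
    for i, name in enumerate(_PYRIMIDINE_RING):
        ang = math.radians(90.0 + 60.0 * i)
        out[name] = np.array([radius * math.cos(ang), radius * math.sin(ang)])
    return out


def _fused_pentagon(a: np.ndarray, b: np.ndarray, away_from: np.ndarray):
    """Regular pentagon sharing edge a-b, bulging away from ``away_from``.

    Returns the three new vertices walking the ring from ``b`` back to ``a``.
    """
    side = float(np.linalg.norm(b - a))
    circ = side / (2.0 * math.sin(math.pi / 5.0))
    apo = circ * math.cos(math.pi / 5.0)
    mid = (a + b) / 2.0
    u = mid - away_from
    u = u / np.linalg.norm(u)
    center = mid + apo * u

    def rot(p, deg):
        t = math.radians(deg)
        d = p - center
        return center + np.array(
            [d[0] * math.cos(t) - d[1] * math.sin(t), d[0] * math.sin(t) + d[1] * math.cos(t)]
        )

    # find rotation direction that carries a onto b in one 72 degree step
    sign = 1.0 if np.linalg.norm(rot(a, 72.0) - b) < 1e-6 else -1.0
    return [rot(a, sign * deg) for deg in (144.0, 216.0, 288.0)]


def _base_template(base: str) -> tuple[list[str], np.ndarray]:
    """Planar idealized geometry of one nucleobase, centered on its ring."""
    if base not in _EXOCYCLIC:
        raise TemplateError(f"no template for base {base!r}")
    ring = _hexagon_ring()
    labels = list(_PYRIMIDINE_RING)
    coords = [ring[name] for name in labels]
    if base in PURINES:
        # imidazole ring fused on the C4-C5 edge: C4-C5-N7-C8-N9
        hex_center = np.zeros(2)
        n7, c8, n9 = _fused_pentagon(ring["C4"], ring["C5"], hex_center)
        # walking on from C5 gives N7 (next to C5), then C8, then N9 (next to C4)
        labels += ["N7", "C8", "N9"]
        coords += [n7, c8, n9]
    ring_center = np.zeros(2)
    by_name = dict(zip(labels, coords))
    for parent, label, bond in _EXOCYCLIC[base]:
        p = by_name[parent]
        direction = p - ring_center
        direction = direction / np.linalg.norm(direction)
        labels.append(label)
        coords.append(p + bond * direction)
    xy = np.asarray(coords, dtype=float)
    return labels, np.column_stack([xy, np.zeros(len(xy))])


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BasePairFrame:
    """One canonical Watson-Crick base pair.

    ``labels[i]``/``strands[i]``/``coords[i]`` describe atom ``i``; strand 1
    carries the (DNA) target base, strand 2 its complement.  Canonical frames
    have their centroid at the origin and all atoms in the xy-plane.
    """

    pair_id: str  # e.g. "A:T"
    strand1_type: str  # "DNA"
    strand2_type: str  # "DNA" | "RNA"
    labels: tuple[str, ...]
    strands: np.ndarray  # int array, 1 or 2
    coords: np.ndarray  # (n_atoms, 3)

    @property
    def base1(self) -> str:
        return self.pair_id.split(":")[0]

    @property
    def base2(self) -> str:
        return self.pair_id.split(":")[1]

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)


@dataclass(frozen=True)
class KmerSystem:
    """``k`` stacked base pairs of one duplex class, with merged coordinates."""

    identifier: str  # "<class>|<strand-1 5'->3'>"
    k: int
    duplex_class: str
    strand1_seq: str
    rise: float
    twist: float
    labels: tuple[str, ...]
    strands: np.ndarray
    pair_index: np.ndarray  # 1-based base-pair index per atom
    coords: np.ndarray

    @property
    def pairs(self) -> tuple[str, ...]:
        comp = COMPLEMENT[self.duplex_class]
        return tuple(f"{b}:{comp[b]}" for b in self.strand1_seq)

    def pair_centroids(self) -> np.ndarray:
        return np.stack(
            [self.coords[self.pair_index == i].mean(axis=0) for i in range(1, self.k + 1)]
        )


# --------------------------------------------------------------------------
# canonical form
# --------------------------------------------------------------------------


def _plane_normal(coords: np.ndarray) -> np.ndarray:
    """Unit normal of the best-fit plane (least-squares, via SVD)."""
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    n = vt[2]
    # resolve the sign ambiguity deterministically
    for c in (n[2], n[1], n[0]):
        if abs(c) > 1e-12:
            return n if c > 0 else -n
    return n


def _rotation_to_z(normal: np.ndarray) -> np.ndarray:
    """Proper rotation carrying ``normal`` onto +z."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(normal, z)
    c = float(np.dot(normal, z))
    s = float(np.linalg.norm(v))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180 degrees about x
        return np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def _pyrimidine_atom(frame_labels, strands, coords, bases, label) -> np.ndarray:
    """Coordinates of atom ``label`` on the (unique) pyrimidine of the pair."""
    for strand, base in ((1, bases[0]), (2, bases[1])):
        if base in PYRIMIDINES:
            for lab, s, xyz in zip(frame_labels, strands, coords):
                if s == strand and lab == label:
                    return xyz
            raise TemplateError(
                f"pyrimidine atom {label!r} not found on strand {strand}"
            )
    raise TemplateError(f"no pyrimidine base in pair {bases[0]}:{bases[1]}")


def _pyrimidine_carbonyl(frame_labels, strands, coords, bases) -> np.ndarray:
    """In-plane C2->O2 vector of the (unique) pyrimidine base of the pair."""
    c2 = _pyrimidine_atom(frame_labels, strands, coords, bases, "C2")
    o2 = _pyrimidine_atom(frame_labels, strands, coords, bases, "O2")
    return o2 - c2


def canonicalize_base_pair(frame: BasePairFrame) -> BasePairFrame:
    """Bring a labeled base pair into canonical orientation.

    Translates the centroid to the origin, rotates the least-squares base
    plane into the xy-plane (normal to +z), and applies the final in-plane
    rotation aligning the pyrimidine C2->O2 carbonyl bond with +x.  The
    remaining two-fold flip ambiguity (a 180-degree rotation about x also
    satisfies those constraints) is resolved by requiring the pyrimidine N1
    glycosidic nitrogen to lie at y >= 0.  Idempotent within 1e-6 A.
    """
    bases = (frame.base1, frame.base2)
    coords = np.asarray(frame.coords, dtype=float)
    coords = coords - coords.mean(axis=0)
    rot = _rotation_to_z(_plane_normal(coords))
    coords = coords @ rot.T
    carbonyl = _pyrimidine_carbonyl(frame.labels, frame.strands, coords, bases)
    theta = math.atan2(carbonyl[1], carbonyl[0])
    c, s = math.cos(-theta), math.sin(-theta)
    rz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    coords = coords @ rz.T
    n1 = _pyrimidine_atom(frame.labels, frame.strands, coords, bases, "N1")
    if n1[1] < 0:
        coords = coords * np.array([1.0, -1.0, -1.0])
    coords = coords - coords.mean(axis=0)
    return replace(frame, coords=coords)


# --------------------------------------------------------------------------
# base-pair frame construction
# --------------------------------------------------------------------------

_PAIR_SEPARATION = 6.0  # Angstrom between the two base-ring centers

_frame_cache: dict[tuple[str, str], BasePairFrame] = {}


def base_pair_frame(strand1_base: str, duplex_class: str) -> BasePairFrame:
    """Canonical frame for one Watson-Crick pair of the given duplex class."""
    if duplex_class not in DUPLEX_CLASSES:
        raise DuplexError(f"unknown duplex class {duplex_class!r}")
    if strand1_base not in DNA_ALPHABET:
        raise TemplateError(f"strand-1 base must be DNA ({strand1_base!r} given)")
    key = (strand1_base, duplex_class)
    if key in _frame_cache:
        return _frame_cache[key]

    base2 = COMPLEMENT[duplex_class][strand1_base]
    lab1, xyz1 = _base_template(strand1_base)
    lab2, xyz2 = _base_template(base2)
    # partner base: mirrored through the yz-plane so the pairing edges face
    # each other, each ring center offset half the pair separation along x
    xyz1 = xyz1 + np.array([-_PAIR_SEPARATION / 2.0, 0.0, 0.0])
    xyz2 = xyz2 * np.array([-1.0, 1.0, 1.0]) + np.array([_PAIR_SEPARATION / 2.0, 0.0, 0.0])

    frame = BasePairFrame(
        pair_id=f"{strand1_base}:{base2}",
        strand1_type="DNA",
        strand2_type=duplex_class.split(":")[1],
        labels=tuple(lab1 + lab2),
        strands=np.array([1] * len(lab1) + [2] * len(lab2)),
        coords=np.vstack([xyz1, xyz2]),
    )
    frame = canonicalize_base_pair(frame)
    _frame_cache[key] = frame
    return frame


# --------------------------------------------------------------------------
# enumeration
# --------------------------------------------------------------------------


def enumerate_kmers(k: int, duplex_classes: Iterable[str]) -> list[str]:
    """All non-chimeric duplex k-mer identifiers, lexicographically ordered.

    A k-mer is identified by its duplex class and strand-1 sequence read
    5'->3' (``"DNA:DNA|AC"``); the complementary strand is implied.
    """
    classes = sorted(set(duplex_classes))
    if not classes:
        raise DuplexError("duplex_classes must be a non-empty set")
    for c in classes:
        if c not in DUPLEX_CLASSES:
            raise DuplexError(f"unknown duplex class {c!r}")
    if not (1 <= int(k) <= MAX_K):
        raise KmerRangeError(f"k must be in 1..{MAX_K}, got {k}")
    out = []
    for cls in classes:
        for seq in product(DNA_ALPHABET, repeat=int(k)):
            out.append(f"{cls}|{''.join(seq)}")
    return sorted(out)


def parse_kmer_id(identifier: str) -> tuple[str, str]:
    """Split ``"<class>|<seq>"`` into (duplex_class, strand1_seq)."""
    try:
        cls, seq = identifier.split("|")
    except ValueError as exc:
        raise DuplexError(f"malformed k-mer identifier {identifier!r}") from exc
    if cls not in DUPLEX_CLASSES or not seq or any(b not in DNA_ALPHABET for b in seq):
        raise DuplexError(f"malformed k-mer identifier {identifier!r}")
    return cls, seq


# --------------------------------------------------------------------------
# geometry builder
# --------------------------------------------------------------------------


def build_geometry(
    kmer_id: str, rise: float = DEFAULT_RISE, twist: float = DEFAULT_TWIST
) -> KmerSystem:
    """Stack canonical base-pair frames into a duplex k-mer.

    Pair ``i`` (1-based) is the canonical frame rotated ``(i-1)*twist``
    degrees about +z and translated ``(i-1)*rise`` Angstrom along +z; pair 1
    is the untransformed template.  Deterministic: identical inputs give
    bit-identical coordinates.
    """
    duplex_class, seq = parse_kmer_id(kmer_id)
    if not (1 <= len(seq) <= MAX_K):
        raise KmerRangeError(f"k must be in 1..{MAX_K}, got {len(seq)}")
    labels: list[str] = []
    strands: list[np.ndarray] = []
    pair_index: list[np.ndarray] = []
    coords: list[np.ndarray] = []
    for i, base in enumerate(seq):
        frame = base_pair_frame(base, duplex_class)
        t = math.radians(twist * i)
        c, s = math.cos(t), math.sin(t)
        rz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        xyz = frame.coords @ rz.T + np.array([0.0, 0.0, rise * i])
        labels.extend(frame.labels)
        strands.append(frame.strands)
        pair_index.append(np.full(len(frame.labels), i + 1))
        coords.append(xyz)
    return KmerSystem(
        identifier=kmer_id,
        k=len(seq),
        duplex_class=duplex_class,
        strand1_seq=seq,
        rise=rise,
        twist=twist,
        labels=tuple(labels),
        strands=np.concatenate(strands),
        pair_index=np.concatenate(pair_index),
        coords=np.vstack(coords),
    )


def pair_orientation_degrees(system: KmerSystem, pair: int) -> float:
    """In-plane orientation of base pair ``pair`` (1-based), in degrees.

    Measured as the xy-angle of the pair's pyrimidine C2->O2 carbonyl bond,
    which is 0 for the canonical frame; recovers the applied twist.
    """
    mask = system.pair_index == pair
    labels = [l for l, m in zip(system.labels, mask) if m]
    strands = system.strands[mask]
    coords = system.coords[mask]
    comp = COMPLEMENT[system.duplex_class]
    b1 = system.strand1_seq[pair - 1]
    v = _pyrimidine_carbonyl(labels, strands, coords, (b1, comp[b1]))
    return math.degrees(math.atan2(v[1], v[0])) % 360.0


def measure_rise(system: KmerSystem) -> np.ndarray:
    """Consecutive base-pair centroid separations along z (length k-1)."""
    cz = system.pair_centroids()[:, 2]
    return np.diff(cz)


def measure_twist(system: KmerSystem) -> np.ndarray:
    """Consecutive inter-pair frame rotations about z, degrees (length k-1)."""
    angles = [pair_orientation_degrees(system, i) for i in range(1, system.k + 1)]
    return np.array([(b - a) % 360.0 for a, b in zip(angles, angles[1:])])


# --------------------------------------------------------------------------
# structure I/O
# --------------------------------------------------------------------------

_RES_NAME = {("DNA", b): f"D{b}" for b in "ACGT"} | {("RNA", b): b for b in "ACGU"}


def _element(label: str) -> str:
    el = label[0].upper()
    if el not in "CNOHP":
        raise TemplateError(f"cannot resolve element for atom label {label!r}")
    return el


def write_structure(system: KmerSystem, fmt: str = "xyz") -> str:
    """Serialize a built k-mer as XYZ or fixed-column PDB text."""
    fmt = fmt.lower()
    if fmt == "xyz":
        lines = [str(len(system.labels)), system.identifier]
        for lab, xyz in zip(system.labels, system.coords):
            lines.append(
                f"{_element(lab):<2s} {xyz[0]:14.8f} {xyz[1]:14.8f} {xyz[2]:14.8f}"
            )
        return "\n".join(lines) + "\n"
    if fmt == "pdb":
        comp = COMPLEMENT[system.duplex_class]
        lines = [f"TITLE     {system.identifier}"]
        serial = 0
        for strand, chain in ((1, "A"), (2, "B")):
            nuc = "DNA" if strand == 1 else system.duplex_class.split(":")[1]
            for pair in range(1, system.k + 1):
                base1 = system.strand1_seq[pair - 1]
                base = base1 if strand == 1 else comp[base1]
                res = _RES_NAME[(nuc, base)]
                sel = (system.strands == strand) & (system.pair_index == pair)
                for lab, xyz in zip(
                    [l for l, m in zip(system.labels, sel) if m], system.coords[sel]
                ):
                    serial += 1
                    lines.append(
                        f"ATOM  {serial:>5d} {lab:<4s}{res:>4s} {chain}{pair:>4d}    "
                        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                        f"{1.00:6.2f}{0.00:6.2f}          {_element(lab):>2s}"
                    )
        lines.append("END")
        return "\n".join(lines) + "\n"
    raise DuplexError(f"unsupported structure format {fmt!r} (use 'xyz' or 'pdb')")


def read_structure(text: str, fmt: str = "xyz") -> tuple[list[str], np.ndarray]:
    """Read back a structure written by :func:`write_structure`.

    Returns (element symbols, coordinates); used for round-trip checks.
    """
    fmt = fmt.lower()
    if fmt == "xyz":
        lines = text.strip().splitlines()
        n = int(lines[0])
        elements, coords = [], []
        for line in lines[2 : 2 + n]:
            parts = line.split()
            elements.append(parts[0])
            coords.append([float(p) for p in parts[1:4]])
        if len(elements) != n:
            raise DuplexError("XYZ atom count does not match header")
        return elements, np.asarray(coords)
    if fmt == "pdb":
        elements, coords = [], []
        for line in io.StringIO(text):
            if line.startswith(("ATOM", "HETATM")):
                elements.append(line[76:78].strip())
                coords.append(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                )
        return elements, np.asarray(coords)
    raise DuplexError(f"unsupported structure format {fmt!r}")
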