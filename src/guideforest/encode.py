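"""Guide feature encoding: one-hot, counts, raw sequence and quantum blocks.

Transforms 20-nt Cas9 guide (protospacer) sequences into the model's feature
matrix:

* positional one-hot encoding — 4 bits per position x 20 positions plus 16
  bits per adjacent ordered base pair x 19 positions (384 binary columns);
* position-independent counts — 4 single-base and 16 ordered dinucleotide
  counts, plus indicator encoding of the PAM's N nucleotide;
* 'raw' summary features — GC content, Watson-Crick melting temperature,
  sgRNA minimum free energy (via an external folding engine), distance to the
  nearest downstream NGG, and location relative to the target gene;
* quantum k-mer features — sliding windows of k = 1..4 base pairs over the
  guide, each window looked up in a duplex-class-specific quantum property
  table (H-L gap, hydrogen-bond energy, stacking energy, total energy,
  electron count).

Positions are 1-based with position 20 PAM-proximal (the 3' end of the
protospacer).  Assembly min-max normalizes the response to [0, 1] (an affine
map, so distribution skew is preserved) and greedily prunes one member of any
feature pair whose |Pearson r| exceeds 0.9.
"""

from __future__ import annotations

import shutil
import subprocess
import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .duplex import DNA_DNA, DNA_RNA, DUPLEX_CLASSES
from .qproperties import PropertyTable

GUIDE_LENGTH = 20
BASES = ("A", "C", "G", "T")
DINUCLEOTIDES = tuple("".join(p) for p in product(BASES, repeat=2))
GENE_LOCATIONS = ("TSS", "Q1", "Q2", "Q3", "Q4", "TTS")
_GENE_LOCATION_CODE = {loc: i for i, loc in enumerate(GENE_LOCATIONS)}

QUANTUM_PROPERTIES = (
    "hl_gap",
    "hbond_energy",
    "stacking_energy",
    "total_energy",
    "electron_count",
)

PRUNE_THRESHOLD = 0.9
#: provenance tags a feature column may carry
PROVENANCE_TAGS = ("raw", "onehot", "quantum", "species")


class EncodingError(ValueError):
    """Invalid guide content or failed feature computation."""


class AssemblyError(ValueError):
    """Feature-matrix assembly failure (NaNs, constant response, ...)."""


# --------------------------------------------------------------------------
# guides
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Guide:
    """A 20-nt target-strand protospacer with optional context and response."""

    seq: str
    pam: str | None = None
    efficiency: float | None = None
    distance_to_pam: int | None = None
    gene_location: str | None = None
    species: str | None = None

    def __post_init__(self):
        if len(self.seq) != GUIDE_LENGTH:
            raise EncodingError(
                f"guide must be {GUIDE_LENGTH} nt, got {len(self.seq)}: {self.seq!r}"
            )
        for i, b in enumerate(self.seq):
            if b not in BASES:
                raise EncodingError(f"non-ACGT base {b!r} at position {i + 1}")
        if self.pam is not None:
            if len(self.pam) != 3 or self.pam[0] not in BASES or self.pam[1:] != "GG":
                raise EncodingError(f"PAM must match NGG, got {self.pam!r}")
        if self.gene_location is not None and self.gene_location not in GENE_LOCATIONS:
            raise EncodingError(
                f"gene_location must be one of {GENE_LOCATIONS}, got {self.gene_location!r}"
            )
        if self.distance_to_pam is not None and self.distance_to_pam < 0:
            raise EncodingError("distance_to_pam must be >= 0")


def _as_guides(guides: Iterable[Guide | str]) -> list[Guide]:
    return [g if isinstance(g, Guide) else Guide(seq=g) for g in guides]


# --------------------------------------------------------------------------
# positional one-hot block
# --------------------------------------------------------------------------

ONEHOT_COLUMNS = tuple(
    [f"{b}@{p}" for p in range(1, GUIDE_LENGTH + 1) for b in BASES]
    + [f"{d}@{p}" for p in range(1, GUIDE_LENGTH) for d in DINUCLEOTIDES]
)
N_ONEHOT_FEATURES = len(ONEHOT_COLUMNS)  # 384
ONEHOT_BITS_PER_GUIDE = GUIDE_LENGTH + (GUIDE_LENGTH - 1)  # 39

_BASE_IDX = {b: i for i, b in enumerate(BASES)}
_DI_IDX = {d: i for i, d in enumerate(DINUCLEOTIDES)}


def onehot_positional(guides: Iterable[Guide | str]) -> pd.DataFrame:
    """Binary positional encoding: one column per base@position and pair@position."""
    gs = _as_guides(guides)
    out = np.zeros((len(gs), N_ONEHOT_FEATURES), dtype=np.int8)
    for r, g in enumerate(gs):
        for p, b in enumerate(g.seq):
            out[r, p * 4 + _BASE_IDX[b]] = 1
        for p in range(GUIDE_LENGTH - 1):
            di = g.seq[p : p + 2]
            out[r, 4 * GUIDE_LENGTH + p * 16 + _DI_IDX[di]] = 1
    return pd.DataFrame(out, columns=list(ONEHOT_COLUMNS))


# --------------------------------------------------------------------------
# position-independent counts
# --------------------------------------------------------------------------


def position_independent_counts(guides: Iterable[Guide | str]) -> pd.DataFrame:
    """Single-base and ordered-dinucleotide counts, plus PAM-N indicators.

    Single counts sum to 20 and overlapping-pair counts to 19 per guide.  The
    four ``pam_N=`` indicator columns appear only when every guide carries a
    PAM annotation.
    """
    gs = _as_guides(guides)
    cols = [f"count_{b}" for b in BASES] + [f"count_{d}" for d in DINUCLEOTIDES]
    with_pam = all(g.pam is not None for g in gs) and len(gs) > 0
    if with_pam:
        cols += [f"pam_N={b}" for b in BASES]
    out = np.zeros((len(gs), len(cols)), dtype=np.int64)
    for r, g in enumerate(gs):
        for b in g.seq:
            out[r, _BASE_IDX[b]] += 1
        for p in range(GUIDE_LENGTH - 1):
            out[r, 4 + _DI_IDX[g.seq[p : p + 2]]] += 1
        if with_pam:
            out[r, 20 + _BASE_IDX[g.pam[0]]] = 1
    return pd.DataFrame(out, columns=cols)


# --------------------------------------------------------------------------
# raw features
# --------------------------------------------------------------------------


def gc_content(seq: str) -> float:
    """Fraction of the sequence that is G or C, in [0, 1]."""
    if not seq:
        raise EncodingError("empty sequence")
    return sum(b in "GC" for b in seq) / len(seq)


def tm_watson_crick(seq: str) -> float:
    """Watson-Crick duplex melting temperature, degrees C.

    ``Tm = 64.9 + 41 * (nG + nC - 16.4) / (nA + nT + nG + nC)``.
    """
    if not seq:
        raise EncodingError("empty sequence (Tm undefined)")
    n_gc = sum(b in "GC" for b in seq)
    return 64.9 + 41.0 * (n_gc - 16.4) / len(seq)


class MfeUnavailable(RuntimeError):
    """No folding engine is configured/usable for MFE features."""


class NullMfe:
    """Explicit 'no MFE provider' state: raises on use."""

    available = False

    def mfe(self, seq: str) -> float:
        raise MfeUnavailable("no minimum-free-energy provider configured")


class RNAfoldMfe:
    """Minimum free energy of the guide spacer folded as RNA, via RNAfold."""

    def __init__(self, executable: str = "RNAfold"):
        self.executable = executable

    @property
    def available(self) -> bool:
        return shutil.which(self.executable) is not None

    def mfe(self, seq: str) -> float:
        rna = seq.replace("T", "U")
        proc = subprocess.run(
            [self.executable, "--noPS"],
            input=rna + "\n",
            capture_output=True,
            text=True,
            check=True,
        )
        # last line: "....struct.... ( -1.20)"
        tail = proc.stdout.strip().splitlines()[-1]
        return float(tail[tail.rindex("(") + 1 : tail.rindex(")")])


def default_mfe_provider():
    prov = RNAfoldMfe()
    return prov if prov.available else NullMfe()


RAW_FEATURE_NAMES = ("gc", "tm", "mfe", "distance_to_pam", "gene_location")
N_RAW_FEATURES = len(RAW_FEATURE_NAMES)  # 5


def raw_features(
    guides: Iterable[Guide | str],
    mfe_provider=None,
    features: Sequence[str] = RAW_FEATURE_NAMES,
    expand_gene_location: bool = False,
) -> pd.DataFrame:
    """The five raw summary features per guide.

    ``gene_location`` is a single ordinal column coding position along the
    gene (TSS=0, Q1..Q4=1..4, TTS=5); pass ``expand_gene_location=True`` for
    six one-hot indicator columns instead (still one raw *feature*).  Missing
    genome context or an unavailable MFE provider raises an explicit
    feature-level error rather than silently emitting zeros; drop the feature
    from ``features`` to opt out (with a warning for MFE).
    """
    gs = _as_guides(guides)
    unknown = [f for f in features if f not in RAW_FEATURE_NAMES]
    if unknown:
        raise EncodingError(f"unknown raw feature(s): {unknown}")
    if mfe_provider is None:
        mfe_provider = default_mfe_provider()

    data: dict[str, list] = {}
    if "gc" in features:
        data["gc"] = [gc_content(g.seq) for g in gs]
    if "tm" in features:
        data["tm"] = [tm_watson_crick(g.seq) for g in gs]
    if "mfe" in features:
        if not getattr(mfe_provider, "available", True):
            warnings.warn(
                "MFE provider unavailable; 'mfe' column omitted from raw block",
                stacklevel=2,
            )
        else:
            data["mfe"] = [mfe_provider.mfe(g.seq) for g in gs]
    if "distance_to_pam" in features:
        missing = [i for i, g in enumerate(gs) if g.distance_to_pam is None]
        if missing:
            raise EncodingError(
                f"distance_to_pam requested but absent for guide row(s) {missing[:5]}"
            )
        data["distance_to_pam"] = [g.distance_to_pam for g in gs]
    if "gene_location" in features:
        missing = [i for i, g in enumerate(gs) if g.gene_location is None]
        if missing:
            raise EncodingError(
                f"gene_location requested but absent for guide row(s) {missing[:5]}"
            )
        if expand_gene_location:
            for loc in GENE_LOCATIONS:
                data[f"gene_location={loc}"] = [
                    int(g.gene_location == loc) for g in gs
                ]
        else:
            data["gene_location"] = [_GENE_LOCATION_CODE[g.gene_location] for g in gs]
    return pd.DataFrame(data)


# --------------------------------------------------------------------------
# quantum sliding-window block
# --------------------------------------------------------------------------


def quantum_window_count(k_set: Iterable[int]) -> int:
    """Number of sliding windows per property and class: sum_k (21 - k)."""
    return sum(GUIDE_LENGTH + 1 - k for k in k_set)


def quantum_positional(
    guides: Iterable[Guide | str],
    table: PropertyTable,
    k_set: Sequence[int] = (1, 2, 3, 4),
    classes: Sequence[str] = DUPLEX_CLASSES,
    properties: Sequence[str] = QUANTUM_PROPERTIES,
    method_tag: str | None = None,
) -> pd.DataFrame:
    """Quantum k-mer descriptors over sliding windows of the guide.

    For each k in ``k_set``, window start p in 1..(21-k), duplex class and
    property, one real-valued column ``<prop>|<class>|k<k>|p<p>`` holding the
    table value for the window's strand-1 sequence.  The table must cover
    every k-mer encountered; a gap raises a lookup error naming it.
    """
    gs = _as_guides(guides)
    k_set = sorted(set(int(k) for k in k_set))
    if any(k < 1 or k > 4 for k in k_set):
        raise EncodingError(f"k_set must be within 1..4, got {k_set}")
    columns: dict[str, np.ndarray] = {}
    for prop in properties:
        for cls in classes:
            lut = table.property_lookup(prop, cls, method_tag)
            for k in k_set:
                for p in range(1, GUIDE_LENGTH + 2 - k):
                    vals = np.empty(len(gs))
                    for r, g in enumerate(gs):
                        mer = g.seq[p - 1 : p - 1 + k]
                        try:
                            vals[r] = lut[mer]
                        except KeyError:
                            raise KeyError(
                                f"property table has no record for ({mer}, {cls})"
                            ) from None
                    columns[f"{prop}|{cls}|k{k}|p{p}"] = vals
    return pd.DataFrame(columns)


# --------------------------------------------------------------------------
# assembly: normalization + correlation pruning
# --------------------------------------------------------------------------


def minmax_normalize(y: np.ndarray) -> np.ndarray:
    """Affine min-max scaling to [0, 1]; preserves distribution shape."""
    y = np.asarray(y, dtype=float)
    lo, hi = np.min(y), np.max(y)
    if hi == lo:
        raise AssemblyError("response vector is constant; min-max scaling undefined")
    return (y - lo) / (hi - lo)


def prune_correlated(X: pd.DataFrame, threshold: float = PRUNE_THRESHOLD) -> list[str]:
    """Greedy correlation pruning; returns the retained column names.

    Columns are scanned in their declared order; a column is kept only if its
    |Pearson r| with every previously kept column is <= ``threshold`` (the
    earlier member of a violating pair survives).  Constant columns correlate
    with nothing by convention.  Deterministic and idempotent.
    """
    vals = X.to_numpy(dtype=float)
    n = vals.shape[0]
    centered = vals - vals.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    kept_idx: list[int] = []
    for j in range(vals.shape[1]):
        if norms[j] == 0:
            kept_idx.append(j)
            continue
        ok = True
        if kept_idx:
            prev = np.array(kept_idx)
            live = prev[norms[prev] > 0]
            if live.size:
                r = centered[:, live].T @ centered[:, j] / (norms[live] * norms[j])
                r = np.clip(r, -1.0, 1.0)
                if np.any(np.abs(r) > threshold):
                    ok = False
        if ok:
            kept_idx.append(j)
    return [X.columns[j] for j in kept_idx]


@dataclass
class FeatureMatrix:
    """Guides x features with per-column provenance and normalized response."""

    X: pd.DataFrame
    provenance: pd.Series  # column name -> tag in PROVENANCE_TAGS
    y: pd.Series | None = None  # min-max normalized response in [0, 1]
    y_raw: pd.Series | None = None

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def columns_with_tag(self, tag: str) -> list[str]:
        return [c for c in self.X.columns if self.provenance[c] == tag]

    def write(self, path: str | Path, header_comment: str | None = None) -> None:
        """TSV matrix plus a ``.provenance.tsv`` sidecar of column tags."""
        path = Path(path)
        out = self.X.copy()
        if self.y is not None:
            out.insert(0, "response", self.y.to_numpy())
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            out.to_csv(fh, sep="\t", index=False)
        side = path.with_suffix(path.suffix + ".provenance.tsv")
        self.provenance.rename("provenance").rename_axis("feature").to_csv(side, sep="\t")


def assemble_matrix(
    guides: Sequence[Guide | str],
    blocks: Mapping[str, pd.DataFrame],
    prune_threshold: float = PRUNE_THRESHOLD,
    require_response: bool = True,
) -> FeatureMatrix:
    """Concatenate tagged feature blocks into a pruned, normalized matrix.

    ``blocks`` maps a provenance tag (``raw``/``onehot``/``quantum``) to its
    block, concatenated in the given order (which also fixes pruning
    priority).  When two or more species tags are present among the guides a
    binary species indicator block is appended.
    """
    gs = _as_guides(guides)
    parts, tags = [], []
    for tag, df in blocks.items():
        if tag not in PROVENANCE_TAGS:
            raise AssemblyError(f"unknown block tag {tag!r}")
        if len(df) != len(gs):
            raise AssemblyError(
                f"block {tag!r} has {len(df)} rows for {len(gs)} guides"
            )
        parts.append(df.reset_index(drop=True))
        tags.extend([tag] * df.shape[1])
    species = sorted({g.species for g in gs if g.species is not None})
    if len(species) >= 2:
        for sp in species[1:]:
            parts.append(
                pd.DataFrame({f"species={sp}": [int(g.species == sp) for g in gs]})
            )
            tags.append("species")
    X = pd.concat(parts, axis=1)
    if X.columns.duplicated().any():
        raise AssemblyError(
            f"duplicate column names across blocks: "
            f"{list(X.columns[X.columns.duplicated()])[:5]}"
        )
    bad = X.columns[X.isna().any()].tolist()
    if bad:
        raise AssemblyError(f"NaN values in feature column(s): {bad[:10]}")
    provenance = pd.Series(tags, index=X.columns)

    kept = prune_correlated(X, prune_threshold)
    X = X[kept]
    provenance = provenance[kept]

    y = y_raw = None
    have_y = [g.efficiency is not None for g in gs]
    if any(have_y):
        if not all(have_y):
            raise AssemblyError("some guides have efficiency scores and some do not")
        y_raw = pd.Series([g.efficiency for g in gs], name="efficiency")
        y = pd.Series(minmax_normalize(y_raw.to_numpy()), name="response")
    elif require_response:
        raise AssemblyError("no efficiency responses present on the guides")
    return FeatureMatrix(X=X, provenance=provenance, y=y, y_raw=y_raw)


#: named feature-set presets for model configuration
FEATURE_SET_PRESETS = {
    "raw": ("raw",),
    "onehot": ("onehot",),
    "qct": ("quantum",),
    "raw+onehot": ("raw", "onehot"),
    "raw+qct": ("raw", "quantum"),
    "onehot+qct": ("onehot", "quantum"),
    "full": ("raw", "onehot", "quantum"),
}


def encode_guides(
    guides: Sequence[Guide | str],
    feature_sets: Sequence[str] = ("onehot",),
    table: PropertyTable | None = None,
    k_set: Sequence[int] = (1, 2, 3, 4),
    classes: Sequence[str] = DUPLEX_CLASSES,
    mfe_provider=None,
    raw_feature_names: Sequence[str] = RAW_FEATURE_NAMES,
    prune_threshold: float = PRUNE_THRESHOLD,
    require_response: bool = True,
) -> FeatureMatrix:
    """One-call encoder: build the requested blocks and assemble the matrix.

    ``feature_sets`` lists block tags (``raw``, ``onehot``, ``quantum``) or a
    preset name from :data:`FEATURE_SET_PRESETS`.  The one-hot block includes
    the position-independent counts.
    """
    wanted: list[str] = []
    for fs in feature_sets:
        wanted.extend(FEATURE_SET_PRESETS.get(fs, (fs,)))
    blocks: dict[str, pd.DataFrame] = {}
    for tag in ("raw", "onehot", "quantum"):  # declared pruning order
        if tag not in wanted:
            continue
        if tag == "raw":
            blocks["raw"] = raw_features(
                guides, mfe_provider=mfe_provider, features=raw_feature_names
            )
        elif tag == "onehot":
            blocks["onehot"] = pd.concat(
                [onehot_positional(guides), position_independent_counts(guides)], axis=1
            )
        else:
            if table is None:
                raise AssemblyError("quantum features requested without a property table")
            blocks["quantum"] = quantum_positional(
                guides, table, k_set=k_set, classes=classes
            )
    return assemble_matrix(
        guides, blocks, prune_threshold=prune_threshold, require_response=require_response
    )


# --------------------------------------------------------------------------
# guide I/O
# --------------------------------------------------------------------------

_GUIDE_COLUMNS = ("seq", "efficiency", "pam", "distance_to_pam", "gene_location", "species")


def read_guides_tsv(path: str | Path) -> list[Guide]:
    """Guides from TSV with a ``seq`` column and optional context columns."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "seq" not in df.columns:
        raise EncodingError(f"{path}: guide table needs a 'seq' column")
    guides = []
    for row in df.itertuples(index=False):
        kw = {}
        for col in _GUIDE_COLUMNS[1:]:
            if col in df.columns:
                val = getattr(row, col)
                if pd.notna(val):
                    kw[col] = int(val) if col == "distance_to_pam" else val
        guides.append(Guide(seq=row.seq, **kw))
    return guides


def read_guides_fasta(path: str | Path) -> list[Guide]:
    """Guides from FASTA of 20-nt records (no responses)."""
    from Bio import SeqIO

    return [Guide(seq=str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_guides_tsv(guides: Sequence[Guide], path: str | Path) -> None:
    rows = [{c: getattr(g, c) for c in _GUIDE_COLUMNS} for g in guides]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
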