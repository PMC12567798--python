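"""Sequence descriptor families for toxicity prediction.

Eight classical composition/order descriptor families (1920 columns at
default parameters), an AAindex physicochemical profile family, the
six-group residue counts plus sequence length, and the `featurize`
driver that assembles the full feature matrix (descriptors + PSSM
pooling + minimotif flags) as a pandas DataFrame indexed by sequence id.

Family dimensions at defaults:

====================  =====  =============================================
amino acid comp.        20   relative residue frequencies
dipeptide comp.        400   overlapping pair frequencies
autocorrelation        720   Moreau–Broto, Moran, Geary x 8 indices x 30 lags
CTD                    147   21 composition + 21 transition + 105 distribution
conjoint triad         343   7-class contiguous triad frequencies
sequence order         160   60 coupling numbers + 100 quasi-sequence-order
PAAC                    50   pseudo amino-acid composition (lambda=30)
APAAC                   80   amphiphilic PAAC (lambda=30)
====================  =====  =============================================

Feature names follow the conventions of the protr descriptor library so
published selected-feature lists (see ``data/selected_features_manifest.tsv``)
map onto columns; the three autocorrelation methods share per-index names
and are disambiguated with ``mb.``/``moran.``/``geary.`` prefixes.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._aadata import (
    AA_GROUPS,
    ALPHABET,
    CTD_PROPERTIES,
    HYDROPHILICITY,
    HYDROPHOBICITY,
    SIDE_CHAIN_MASS,
    TRIAD_CLASSES,
    encode,
    grantham_matrix,
    schneider_wrede_matrix,
    standardized_scale,
)
from .sequence_io import Dataset

__all__ = [
    "DescriptorConfig",
    "AAIndexTable",
    "aac",
    "dpc",
    "ctd",
    "conjoint_triad",
    "autocorrelation",
    "qso_socn",
    "paac_apaac",
    "aaindex_profile",
    "aa_groups_length",
    "featurize",
    "load_feature_manifest",
    "resolve_manifest",
]

#: Default autocorrelation physicochemical indices (AAindex accessions).
DEFAULT_AUTOCORR_INDICES = (
    "CIDH920105",
    "BHAR880101",
    "CHAM820101",
    "CHAM820102",
    "CHOC760101",
    "BIGC670101",
    "CHAM810101",
    "DAYM780201",
)

_AUTOCORR_METHODS = ("moreau-broto", "moran", "geary")
_METHOD_PREFIX = {"moreau-broto": "mb", "moran": "moran", "geary": "geary"}


def _bundled(name: str) -> Path:
    return Path(resources.files("seqtox.data") / name)


# ---------------------------------------------------------------------------
# AAindex flat-file handling
# ---------------------------------------------------------------------------


class AAIndexTable:
    """Parsed AAindex1 flat file: accession -> 20 values in alphabet order.

    Records with missing (``NA``) residue values are skipped, as are
    malformed value blocks.  Iteration order is file order.
    """

    def __init__(self, indices: Mapping[str, np.ndarray]):
        self.indices = dict(indices)

    def __len__(self) -> int:
        return len(self.indices)

    def __contains__(self, acc: str) -> bool:
        return acc in self.indices

    def __getitem__(self, acc: str) -> np.ndarray:
        return self.indices[acc]

    def accessions(self) -> list[str]:
        return list(self.indices)

    @classmethod
    def from_file(cls, path: str | Path) -> "AAIndexTable":
        # AAindex1 "I" block lists values in the order
        # A R N D C Q E G H I / L K M F P S T W Y V.
        order = "ARNDCQEGHILKMFPSTWYV"
        indices: dict[str, np.ndarray] = {}
        acc: str | None = None
        values: list[float] = []
        reading = False
        any_record = False
        with open(path) as fh:
            for line in fh:
                if line.startswith("H "):
                    acc = line[2:].strip().split()[0]
                    values, reading = [], False
                    any_record = True
                elif line.startswith("I "):
                    reading = True
                elif line.startswith("//"):
                    if acc and len(values) == 20 and not any(np.isnan(values)):
                        arr = np.empty(20)
                        for aa, v in zip(order, values):
                            arr[ALPHABET.index(aa)] = v
                        indices[acc] = arr
                    acc, values, reading = None, [], False
                elif reading:
                    for tok in line.split():
                        values.append(float("nan") if tok == "NA" else float(tok))
        if not any_record:
            raise ValueError(f"{path}: no AAindex records found")
        return cls(indices)


def default_aaindex_table() -> AAIndexTable:
    """The bundled stand-in AAindex excerpt (see its file header)."""
    return AAIndexTable.from_file(_bundled("aaindex1_synthetic_subset.txt"))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_ALL_FAMILIES = (
    "aac",
    "dpc",
    "autocorrelation",
    "ctd",
    "ctriad",
    "seqorder",
    "paac",
    "apaac",
    "pssm",
    "groups",
    "motifs",
    "aaindex",
)


@dataclasses.dataclass
class DescriptorConfig:
    """Parameters controlling the descriptor families.

    ``autocorr_nlag``, ``paac_lambda`` and ``qso_nlag`` must be smaller
    than the shortest sequence being featurized (enforced per sequence).
    """

    families: tuple[str, ...] = _ALL_FAMILIES
    autocorr_nlag: int = 30
    autocorr_indices: tuple[str, ...] = DEFAULT_AUTOCORR_INDICES
    paac_lambda: int = 30
    paac_w: float = 0.05
    qso_nlag: int = 30
    qso_w: float = 0.1
    aaindex_path: str | None = None
    ctriad_convention: str = "relative-frequency"

    def __post_init__(self) -> None:
        if self.autocorr_nlag < 1 or self.paac_lambda < 0 or self.qso_nlag < 1:
            raise ValueError("lag/lambda parameters must be positive")
        unknown = set(self.families) - set(_ALL_FAMILIES)
        if unknown:
            raise ValueError(f"unknown descriptor families: {sorted(unknown)}")

    def aaindex_table(self) -> AAIndexTable:
        if self.aaindex_path is None:
            return default_aaindex_table()
        return AAIndexTable.from_file(self.aaindex_path)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["families"] = list(self.families)
        d["autocorr_indices"] = list(self.autocorr_indices)
        return d


# ---------------------------------------------------------------------------
# Individual families.  Public functions accept a sequence string and
# return a pandas Series; _*_values helpers work on integer codes.
# ---------------------------------------------------------------------------


def _require(seq: str, min_len: int, what: str) -> np.ndarray:
    if len(seq) < min_len:
        raise ValueError(f"{what} requires length >= {min_len}, got {len(seq)}")
    return encode(seq)


_AAC_NAMES = list(ALPHABET)


def aac(seq: str) -> pd.Series:
    """Amino-acid composition: 20 relative frequencies (sums to 1)."""
    codes = _require(seq, 1, "aac")
    return pd.Series(np.bincount(codes, minlength=20) / len(codes), index=_AAC_NAMES)


_DPC_NAMES = [a + b for a in ALPHABET for b in ALPHABET]


def dpc(seq: str) -> pd.Series:
    """Overlapping dipeptide composition: 400 relative frequencies."""
    codes = _require(seq, 2, "dpc")
    pairs = codes[:-1] * 20 + codes[1:]
    return pd.Series(np.bincount(pairs, minlength=400) / (len(codes) - 1), index=_DPC_NAMES)


def _ctd_tables() -> list[np.ndarray]:
    tables = []
    for _, groups in CTD_PROPERTIES:
        lut = np.zeros(20, dtype=np.int64)
        for g, members in enumerate(groups, start=1):
            for aa in members:
                lut[ALPHABET.index(aa)] = g
        tables.append(lut)
    return tables


_CTD_LUTS = _ctd_tables()
_CTD_FRACTIONS = (0.0, 0.25, 0.5, 0.75, 1.0)


def _ctd_names() -> list[str]:
    names = []
    for name, _ in CTD_PROPERTIES:
        names += [f"{name}.Group{g}" for g in (1, 2, 3)]
    for i in range(1, 8):
        names += [f"prop{i}.Tr1221", f"prop{i}.Tr1331", f"prop{i}.Tr2332"]
    for i in range(1, 8):
        for g in (1, 2, 3):
            names += [f"prop{i}.G{g}.residue{int(f * 100)}" for f in _CTD_FRACTIONS]
    return names


_CTD_NAMES = _ctd_names()


def ctd(seq: str) -> pd.Series:
    """Composition/transition/distribution over 7 three-class encodings.

    Composition: fraction of residues per class.  Transition: fraction of
    adjacent residue pairs crossing two given classes (unordered).
    Distribution: percent position within the sequence of the first, 25%,
    50%, 75% and last occurrence of each class (0 when the class is
    absent).
    """
    codes = _require(seq, 1, "ctd")
    L = len(codes)
    comp, trans, dist = [], [], []
    for lut in _CTD_LUTS:
        cls = lut[codes]
        counts = np.bincount(cls, minlength=4)[1:]
        comp += list(counts / L)
        if L > 1:
            a, b = cls[:-1], cls[1:]
            for g1, g2 in ((1, 2), (1, 3), (2, 3)):
                n = np.sum(((a == g1) & (b == g2)) | ((a == g2) & (b == g1)))
                trans.append(n / (L - 1))
        else:
            trans += [0.0, 0.0, 0.0]
        for g in (1, 2, 3):
            pos = np.flatnonzero(cls == g) + 1  # 1-based
            if pos.size == 0:
                dist += [0.0] * 5
            else:
                n = pos.size
                picks = [1, max(1, round(0.25 * n)), max(1, round(0.5 * n)),
                         max(1, round(0.75 * n)), n]
                dist += [pos[k - 1] / L * 100.0 for k in picks]
    return pd.Series(comp + trans + dist, index=_CTD_NAMES)


_TRIAD_LUT = np.zeros(20, dtype=np.int64)
for _g, _members in enumerate(TRIAD_CLASSES):
    for _aa in _members:
        _TRIAD_LUT[ALPHABET.index(_aa)] = _g

_TRIAD_NAMES = [
    f"VS{i}{j}{k}" for i in range(1, 8) for j in range(1, 8) for k in range(1, 8)
]


def conjoint_triad(seq: str) -> pd.Series:
    """Conjoint-triad frequencies over 7 physicochemical residue classes.

    Values are relative frequencies (triad count / (L-2)); the
    convention is recorded in :class:`DescriptorConfig`.
    """
    codes = _require(seq, 3, "conjoint triad")
    cls = _TRIAD_LUT[codes]
    idx = cls[:-2] * 49 + cls[1:-1] * 7 + cls[2:]
    return pd.Series(np.bincount(idx, minlength=343) / (len(codes) - 2), index=_TRIAD_NAMES)


def _autocorr_values(codes: np.ndarray, profile: np.ndarray, method: str, nlag: int) -> np.ndarray:
    """One property's autocorrelation values for lags 1..nlag.

    Zero-variance guards: Moran and Geary are defined as 0 when their
    denominator vanishes (constant profile along the sequence).
    """
    x = profile[codes]
    L = len(x)
    out = np.empty(nlag)
    xbar = x.mean()
    dev = x - xbar
    tiny = 1e-12  # constant-profile guard (profiles are standardized, O(1))
    if method == "moreau-broto":
        for d in range(1, nlag + 1):
            out[d - 1] = np.dot(x[:-d], x[d:]) / (L - d)
    elif method == "moran":
        den = np.dot(dev, dev) / L
        for d in range(1, nlag + 1):
            out[d - 1] = 0.0 if den < tiny else (np.dot(dev[:-d], dev[d:]) / (L - d)) / den
    elif method == "geary":
        den = np.dot(dev, dev) / (L - 1) if L > 1 else 0.0
        for d in range(1, nlag + 1):
            diff = x[:-d] - x[d:]
            out[d - 1] = 0.0 if den < tiny else (np.dot(diff, diff) / (2 * (L - d))) / den
    else:
        raise ValueError(f"unknown autocorrelation method {method!r}")
    return out


def _autocorr_profiles(
    indices: Sequence[str], table: AAIndexTable | None
) -> dict[str, np.ndarray]:
    table = table if table is not None else default_aaindex_table()
    profiles = {}
    for acc in indices:
        if acc not in table:
            raise ValueError(f"autocorrelation index {acc!r} missing from AAindex table")
        v = table[acc]
        s = v.std()
        profiles[acc] = (v - v.mean()) / s if s > 0 else np.zeros(20)
    return profiles


def autocorrelation(
    seq: str,
    method: str = "moreau-broto",
    indices: Sequence[str] = DEFAULT_AUTOCORR_INDICES,
    nlag: int = 30,
    table: AAIndexTable | None = None,
) -> pd.Series:
    """Normalized Moreau–Broto, Moran or Geary autocorrelation.

    Property values are standardized over the alphabet before the lagged
    sums; output has ``len(indices) * nlag`` entries named
    ``<prefix>.<accession>.lag<d>``.
    """
    if len(seq) <= nlag:
        raise ValueError(
            f"autocorrelation requires length > nlag={nlag}, got {len(seq)}"
        )
    codes = encode(seq)
    prefix = _METHOD_PREFIX[method] if method in _METHOD_PREFIX else None
    if prefix is None:
        raise ValueError(f"unknown autocorrelation method {method!r}")
    profiles = _autocorr_profiles(indices, table)
    values, names = [], []
    for acc in indices:
        values.append(_autocorr_values(codes, profiles[acc], method, nlag))
        names += [f"{prefix}.{acc}.lag{d}" for d in range(1, nlag + 1)]
    return pd.Series(np.concatenate(values), index=names)


_DIST_MATRICES = {"Schneider": schneider_wrede_matrix(), "Grantham": grantham_matrix()}


def _qso_socn_values(codes: np.ndarray, nlag: int, w: float) -> tuple[np.ndarray, list[str]]:
    L = len(codes)
    counts = np.bincount(codes, minlength=20).astype(float)
    socn_vals, socn_names = [], []
    qso_vals, qso_names = [], []
    for mat_name, M in _DIST_MATRICES.items():
        tau = np.empty(nlag)
        for d in range(1, nlag + 1):
            dd = M[codes[:-d], codes[d:]]
            tau[d - 1] = np.dot(dd, dd)
        socn_vals.append(tau)
        socn_names += [f"{mat_name}.lag{d}" for d in range(1, nlag + 1)]
        denom = counts.sum() + w * tau.sum()
        qso_vals.append(counts / denom)
        qso_names += [f"{mat_name}.Xr.{aa}" for aa in ALPHABET]
        qso_vals.append(w * tau / denom)
        qso_names += [f"{mat_name}.Xd.{20 + d}" for d in range(1, nlag + 1)]
    return (
        np.concatenate(socn_vals + qso_vals),
        socn_names + qso_names,
    )


def qso_socn(seq: str, nlag: int = 30, w: float = 0.1) -> pd.Series:
    """Sequence-order coupling numbers and quasi-sequence-order descriptors.

    Computed for both the rebuilt Schneider–Wrede and Grantham distance
    matrices: ``2*nlag`` coupling numbers (squared-distance sums at each
    lag) followed by ``2*(20+nlag)`` quasi-sequence-order values.  At
    ``w=0`` the first 20 quasi-sequence-order values of each matrix
    reduce to amino-acid composition.
    """
    if len(seq) <= nlag:
        raise ValueError(f"qso_socn requires length > nlag={nlag}, got {len(seq)}")
    values, names = _qso_socn_values(encode(seq), nlag, w)
    return pd.Series(values, index=names)


_PAAC_SCALES = [
    standardized_scale(HYDROPHOBICITY),
    standardized_scale(HYDROPHILICITY),
    standardized_scale(SIDE_CHAIN_MASS),
]
_APAAC_SCALE_NAMES = ("Hydrophobicity", "Hydrophilicity")


def _paac_values(codes: np.ndarray, lam: int, w: float) -> tuple[np.ndarray, list[str]]:
    L = len(codes)
    freqs = np.bincount(codes, minlength=20) / L
    theta = np.empty(lam)
    profs = [s[codes] for s in _PAAC_SCALES]
    for d in range(1, lam + 1):
        acc = np.zeros(L - d)
        for p in profs:
            acc += (p[d:] - p[:-d]) ** 2
        theta[d - 1] = acc.mean() / len(_PAAC_SCALES)
    denom = 1.0 + w * theta.sum()
    values = np.concatenate([freqs / denom, w * theta / denom])
    names = [f"Xc1.{aa}" for aa in ALPHABET] + [f"Xc2.lambda.{d}" for d in range(1, lam + 1)]
    return values, names


def _apaac_values(codes: np.ndarray, lam: int, w: float) -> tuple[np.ndarray, list[str]]:
    L = len(codes)
    freqs = np.bincount(codes, minlength=20) / L
    profs = [s[codes] for s in _PAAC_SCALES[:2]]
    taus = np.empty(2 * lam)
    for d in range(1, lam + 1):
        for k, p in enumerate(profs):
            taus[2 * (d - 1) + k] = np.dot(p[:-d], p[d:]) / (L - d)
    denom = 1.0 + w * taus.sum()
    names = [f"Pc1.{aa}" for aa in ALPHABET]
    for d in range(1, lam + 1):
        for scale in _APAAC_SCALE_NAMES:
            names.append(f"Pc2.{scale}.{d}")
    return np.concatenate([freqs / denom, w * taus / denom]), names


def paac_apaac(seq: str, lam: int = 30, w: float = 0.05) -> pd.Series:
    """Pseudo and amphiphilic pseudo amino-acid composition (20+lambda and
    20+2*lambda values).  At ``lam=0`` both reduce to plain composition."""
    if len(seq) <= lam:
        raise ValueError(f"paac_apaac requires length > lambda={lam}, got {len(seq)}")
    codes = encode(seq)
    if lam == 0:
        freqs = np.bincount(codes, minlength=20) / len(codes)
        names = [f"Xc1.{aa}" for aa in ALPHABET] + [f"Pc1.{aa}" for aa in ALPHABET]
        return pd.Series(np.concatenate([freqs, freqs]), index=names)
    pv, pn = _paac_values(codes, lam, w)
    av, an = _apaac_values(codes, lam, w)
    return pd.Series(np.concatenate([pv, av]), index=pn + an)


def aaindex_profile(seq: str, table: AAIndexTable | None = None) -> pd.Series:
    """Mean AAindex value over the sequence, one feature per usable index."""
    codes = _require(seq, 1, "aaindex_profile")
    table = table if table is not None else default_aaindex_table()
    values = [table[acc][codes].mean() for acc in table.accessions()]
    return pd.Series(values, index=table.accessions())


_GROUP_LUTS = [
    np.isin(np.arange(20), [ALPHABET.index(aa) for aa in members])
    for _, members in AA_GROUPS
]
_GROUP_NAMES = [f"count_{name}" for name, _ in AA_GROUPS] + ["length"]


def aa_groups_length(seq: str) -> pd.Series:
    """Counts in six functional residue groups plus sequence length.

    The six groups partition the alphabet, so the counts sum to the
    length.
    """
    codes = _require(seq, 1, "aa_groups_length")
    counts = np.bincount(codes, minlength=20)
    values = [counts[mask].sum() for mask in _GROUP_LUTS] + [len(codes)]
    return pd.Series(np.asarray(values, dtype=float), index=_GROUP_NAMES)


# ---------------------------------------------------------------------------
# Featurization driver
# ---------------------------------------------------------------------------


def featurize(
    ds: Dataset,
    config: DescriptorConfig | None = None,
    pssm_provider=None,
    motif_set=None,
) -> pd.DataFrame:
    """Assemble the full feature matrix for a cleaned dataset.

    Families appear in a fixed order: amino-acid composition, dipeptide
    composition, autocorrelation (Moreau–Broto, Moran, Geary), CTD,
    conjoint triad, sequence order, PAAC, APAAC, PSSM pooling, residue
    group counts + length, minimotif flags, AAindex profiles.  The PSSM
    family needs a provider (see :mod:`seqtox.pssm_features`); when none
    is given the deterministic substitution-matrix fallback is used.
    The motif family is only emitted when a mined
    :class:`~seqtox.motif_mining.MotifSet` is supplied — motifs are
    learned from labels and must come from training data only.

    Any per-family error is re-raised with the offending sequence id.
    """
    from .motif_mining import encode_motifs
    from .pssm_features import FallbackPSSMProvider, gap_pool

    config = config or DescriptorConfig()
    fams = config.families
    table = config.aaindex_table() if ("aaindex" in fams or "autocorrelation" in fams) else None
    if "pssm" in fams and pssm_provider is None:
        pssm_provider = FallbackPSSMProvider()

    rows: list[np.ndarray] = []
    names: list[str] | None = None
    for rec in ds:
        parts: list[pd.Series] = []
        try:
            if "aac" in fams:
                parts.append(aac(rec.sequence))
            if "dpc" in fams:
                parts.append(dpc(rec.sequence))
            if "autocorrelation" in fams:
                for method in _AUTOCORR_METHODS:
                    parts.append(
                        autocorrelation(
                            rec.sequence, method, config.autocorr_indices,
                            config.autocorr_nlag, table,
                        )
                    )
            if "ctd" in fams:
                parts.append(ctd(rec.sequence))
            if "ctriad" in fams:
                parts.append(conjoint_triad(rec.sequence))
            if "seqorder" in fams:
                parts.append(qso_socn(rec.sequence, config.qso_nlag, config.qso_w))
            if "paac" in fams or "apaac" in fams:
                both = paac_apaac(rec.sequence, config.paac_lambda, config.paac_w)
                if "paac" in fams and "apaac" not in fams:
                    both = both[[n for n in both.index if n.startswith("X")]]
                elif "apaac" in fams and "paac" not in fams:
                    both = both[[n for n in both.index if n.startswith("P")]]
                parts.append(both)
            if "pssm" in fams:
                parts.append(gap_pool(pssm_provider.get(rec)))
            if "groups" in fams:
                parts.append(aa_groups_length(rec.sequence))
            if "motifs" in fams and motif_set is not None:
                parts.append(encode_motifs(rec.sequence, motif_set))
            if "aaindex" in fams:
                parts.append(aaindex_profile(rec.sequence, table))
        except ValueError as exc:
            raise ValueError(f"featurizing {rec.id!r}: {exc}") from exc
        vec = pd.concat(parts)
        if names is None:
            names = list(vec.index)
            if len(set(names)) != len(names):
                raise ValueError("duplicate feature names in configuration")
        rows.append(vec.to_numpy())
    if names is None:
        raise ValueError("cannot featurize an empty dataset")
    return pd.DataFrame(np.vstack(rows), index=ds.ids(), columns=names)


# ---------------------------------------------------------------------------
# Selected-feature manifest (published 88-feature list)
# ---------------------------------------------------------------------------

_MANIFEST_PREFIX = {"protr_mb": "mb.", "protr_moran": "moran.", "protr_geary": "geary."}


def load_feature_manifest(path: str | Path | None = None) -> pd.DataFrame:
    """The packaged selected-feature manifest (group, name) as a DataFrame."""
    path = path or _bundled("selected_features_manifest.tsv")
    return pd.read_csv(path, sep="\t")


def resolve_manifest(
    manifest: pd.DataFrame, columns: Iterable[str]
) -> dict[tuple[str, str], str]:
    """Map each (group, name) manifest entry to a unique feature column.

    Autocorrelation entries need their group to disambiguate, because the
    three methods share per-index names; everything else maps by name.
    Raises ``KeyError`` listing unresolved entries.
    """
    colset = set(columns)
    resolved: dict[tuple[str, str], str] = {}
    missing: list[tuple[str, str]] = []
    for group, name in manifest[["group", "name"]].itertuples(index=False):
        candidate = _MANIFEST_PREFIX.get(group, "") + name
        if candidate in colset:
            resolved[(group, name)] = candidate
        else:
            missing.append((group, name))
    if missing:
        raise KeyError(f"unresolved manifest features: {missing}")
    return resolved
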