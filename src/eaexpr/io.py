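"""Domain types and TSV/GMT readers and writers shared by every pipeline stage.

The pipeline works on two-colour-free Illumina-style bead-array summary data:
a probes x samples intensity matrix, a parallel matrix of detection p-values
(probability that the observed intensity arises from background), a sample
sheet assigning each sample to an experimental group and a hybridization
block (chip or mouse pool), and a probe annotation mapping probes to gene
identifiers with a vendor quality label.  Gene identifiers are opaque strings
compared case-sensitively (Entrez-style unique keys); no symbol resolution is
attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("eaexpr")

#: Recognized probe quality labels; anything else coerces to "no_match".
QUALITY_LABELS = ("perfect", "good", "bad", "no_match")

#: Significant digits used when writing numeric matrices.
WRITE_PRECISION = 6


class ValidationError(ValueError):
    """An input file or object violates a structural invariant."""


# ---------------------------------------------------------------------------
# ExpressionExperiment
# ---------------------------------------------------------------------------

@dataclass
class ExpressionExperiment:
    """A probe x sample expression matrix with annotations.

    Attributes
    ----------
    intensities : DataFrame, probes x samples
        Non-negative on the raw scale; arbitrary reals once normalized.
    detection_p : DataFrame or None, probes x samples
        Per probe/sample probability that the intensity is background.
    sample_annot : DataFrame indexed by sample_id
        Columns ``group``, ``block`` (chip or pool id), ``position``.
    probe_annot : DataFrame indexed by probe_id
        Columns ``gene_id`` (nullable) and ``quality``.
    scale : str
        ``"raw"`` or ``"normalized"``.
    """

    intensities: pd.DataFrame
    detection_p: pd.DataFrame | None
    sample_annot: pd.DataFrame
    probe_annot: pd.DataFrame
    scale: str = "raw"

    # -- structural checks --------------------------------------------------

    def validate(self) -> "ExpressionExperiment":
        X = self.intensities
        if X.index.duplicated().any():
            dups = X.index[X.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe_id(s) in matrix: {dups[:5]}")
        missing_samples = [s for s in X.columns if s not in self.sample_annot.index]
        if missing_samples:
            raise ValidationError(
                f"sample sheet is missing sample(s) present in the matrix: {missing_samples}"
            )
        extra = [s for s in self.sample_annot.index if s not in X.columns]
        if extra:
            raise ValidationError(f"sample sheet lists unknown sample(s): {extra}")
        missing_probes = [p for p in X.index if p not in self.probe_annot.index]
        if missing_probes:
            raise ValidationError(
                f"probe annotation is missing probe(s): {missing_probes[:5]}"
            )
        for col in ("group", "block"):
            if col not in self.sample_annot.columns:
                raise ValidationError(f"sample sheet lacks required column '{col}'")
            if self.sample_annot[col].isna().any():
                bad = self.sample_annot.index[self.sample_annot[col].isna()].tolist()
                raise ValidationError(f"sample(s) without {col}: {bad}")
        if self.detection_p is not None:
            D = self.detection_p
            if D.shape != X.shape or list(D.index) != list(X.index) or list(
                D.columns
            ) != list(X.columns):
                raise ValidationError(
                    "detection matrix dimensions/labels disagree with intensity matrix"
                )
            vals = D.to_numpy(dtype=float)
            if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
                raise ValidationError("detection p-values must lie in [0, 1]")
        if self.scale not in ("raw", "normalized"):
            raise ValidationError(f"unknown scale flag {self.scale!r}")
        if self.scale == "raw" and float(X.to_numpy().min()) < 0:
            raise ValidationError("raw-scale intensities must be non-negative")
        # normalize axis labels so round trips compare equal
        X.index.name = "probe_id"
        X.columns.name = "sample_id"
        if self.detection_p is not None:
            self.detection_p.index.name = "probe_id"
            self.detection_p.columns.name = "sample_id"
        # align annotation order with the matrix and coerce quality vocabulary
        self.sample_annot = self.sample_annot.loc[list(X.columns)]
        self.probe_annot = self.probe_annot.loc[list(X.index)].copy()
        qual = self.probe_annot["quality"].astype(str)
        unknown = ~qual.isin(QUALITY_LABELS)
        if unknown.any():
            logger.warning(
                "%d probe(s) with unrecognized quality label coerced to no_match",
                int(unknown.sum()),
            )
            qual[unknown] = "no_match"
        self.probe_annot["quality"] = qual
        return self

    # -- convenience --------------------------------------------------------

    @property
    def n_probes(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    @property
    def groups(self) -> pd.Series:
        return self.sample_annot["group"]

    @property
    def blocks(self) -> pd.Series:
        return self.sample_annot["block"]

    def subset_probes(self, probe_ids) -> "ExpressionExperiment":
        probe_ids = list(probe_ids)
        return replace(
            self,
            intensities=self.intensities.loc[probe_ids],
            detection_p=None if self.detection_p is None else self.detection_p.loc[probe_ids],
            probe_annot=self.probe_annot.loc[probe_ids],
        )

    def gene_universe(self) -> list[str]:
        """Unique non-null gene ids of the (current) platform, sorted."""
        g = self.probe_annot["gene_id"].dropna()
        return sorted(set(g[g != ""]))


# ---------------------------------------------------------------------------
# GeneSetCollection
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets with a provenance note each."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, members in self.sets.items():
            self.sets[name] = frozenset(members)
            self.provenance.setdefault(name, "")

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneSetCollection) and self.sets == other.sets


def apply_exclusion(
    collection: GeneSetCollection, exclude: list[str]
) -> GeneSetCollection:
    """Remove the given gene ids from every set.

    Excluding an id that is absent from a set is a logged no-op; cardinality
    never increases.
    """
    excl = set(exclude)
    out: dict[str, frozenset[str]] = {}
    for name, members in collection.sets.items():
        hits = members & excl
        noops = len(excl - members)
        out[name] = members - excl
        logger.info(
            "apply_exclusion: set %s %d -> %d members (%d removed, %d absent ids)",
            name, len(members), len(out[name]), len(hits), noops,
        )
    return GeneSetCollection(out, dict(collection.provenance))


# ---------------------------------------------------------------------------
# DesignSpec
# ---------------------------------------------------------------------------

@dataclass
class DesignSpec:
    """Group and block factors plus named zero-sum contrasts.

    Contrasts are mappings group -> coefficient; coefficients must sum to
    zero and reference only groups present in the design.
    """

    group: pd.Series           # per sample
    block: pd.Series           # per sample
    contrasts: dict[str, dict[str, float]] = field(default_factory=dict)

    def validate(self) -> "DesignSpec":
        levels = set(self.group.unique())
        for name, coefs in self.contrasts.items():
            unknown = set(coefs) - levels
            if unknown:
                raise ValidationError(
                    f"contrast {name!r} references unknown group(s) {sorted(unknown)}"
                )
            if abs(sum(coefs.values())) > 1e-12:
                raise ValidationError(f"contrast {name!r} coefficients do not sum to 0")
        return self

    @classmethod
    def from_experiment(
        cls, exp: ExpressionExperiment, contrasts: dict[str, dict[str, float]]
    ) -> "DesignSpec":
        return cls(exp.groups, exp.blocks, contrasts).validate()


def parse_contrast(expr: str) -> dict[str, float]:
    """Parse ``"A-B"`` into the contrast mapping {A: +1, B: -1}."""
    a, b = expr.split("-")
    return {a.strip(): 1.0, b.strip(): -1.0}


#: The study's default contrasts: the five spinal-cord contrasts plus the
#: control contrast discussed alongside them.
EAE_CONTRASTS = {
    "MOG4-CFA": parse_contrast("MOG4-CFA"),
    "CFA-WT": parse_contrast("CFA-WT"),
    "OSE4-OSE0": parse_contrast("OSE4-OSE0"),
    "OSE1-OSE0": parse_contrast("OSE1-OSE0"),
    "OSE4-WT": parse_contrast("OSE4-WT"),
    "OSE0-WT": parse_contrast("OSE0-WT"),
}

TH_CONTRASTS = {
    "TH1-TH0": parse_contrast("TH1-TH0"),
    "TH17-TH0": parse_contrast("TH17-TH0"),
}


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

def _read_tsv_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def read_expression(
    matrix_path,
    sample_sheet_path,
    probe_annot_path,
    detection_path=None,
    dialect: str = "separate",
) -> ExpressionExperiment:
    """Read an experiment from TSV files.

    ``dialect="separate"`` expects ``detection_path`` to name a parallel
    probes x samples matrix; ``dialect="interleaved"`` expects the matrix
    file's columns to alternate ``<sample>`` / ``<sample>.Detection``.
    """
    mat = _read_tsv_matrix(matrix_path)
    if mat.index.duplicated().any():
        raise ValidationError(f"duplicate probe_id in {matrix_path}")
    detection = None
    if dialect == "interleaved":
        det_cols = [c for c in mat.columns if c.endswith(".Detection")]
        if not det_cols:
            raise ValidationError(
                f"{matrix_path}: interleaved dialect but no '.Detection' columns"
            )
        samples = [c for c in mat.columns if not c.endswith(".Detection")]
        detection = mat[[s + ".Detection" for s in samples]].copy()
        detection.columns = samples
        mat = mat[samples]
    elif dialect == "separate":
        if detection_path is not None:
            detection = _read_tsv_matrix(detection_path)
            if detection.shape != mat.shape:
                raise ValidationError(
                    f"{detection_path}: detection matrix shape {detection.shape} "
                    f"disagrees with intensity matrix {mat.shape}"
                )
            detection = detection.loc[mat.index, mat.columns]
    else:
        raise ValidationError(f"unknown detection dialect {dialect!r}")

    sheet = pd.read_csv(sample_sheet_path, sep="\t", index_col=0)
    sheet.index = sheet.index.astype(str)
    missing = [s for s in mat.columns if s not in sheet.index]
    if missing:
        raise ValidationError(
            f"{sample_sheet_path}: missing sample(s) {missing} present in {matrix_path}"
        )
    annot = pd.read_csv(probe_annot_path, sep="\t", index_col=0)
    annot.index = annot.index.astype(str)
    missing_p = [p for p in mat.index if p not in annot.index]
    if missing_p:
        raise ValidationError(
            f"{probe_annot_path}: missing probe(s) {missing_p[:5]} present in {matrix_path}"
        )
    if "gene_id" in annot.columns:
        gene = annot["gene_id"]
        annot["gene_id"] = gene.where(~gene.isna(), None)
    exp = ExpressionExperiment(
        intensities=mat,
        detection_p=detection,
        sample_annot=sheet.loc[list(mat.columns)],
        probe_annot=annot.loc[list(mat.index)],
    )
    return exp.validate()


def _fmt(df: pd.DataFrame) -> pd.DataFrame:
    return df.map(lambda v: float(f"%.{WRITE_PRECISION}g" % v))


def write_expression(
    exp: ExpressionExperiment,
    matrix_path,
    sample_sheet_path,
    probe_annot_path,
    detection_path=None,
    dialect: str = "separate",
) -> None:
    """Write an experiment as TSV, numbers at 6 significant digits."""
    if dialect == "interleaved" and exp.detection_p is not None:
        cols = {}
        for s in exp.intensities.columns:
            cols[s] = exp.intensities[s]
            cols[s + ".Detection"] = exp.detection_p[s]
        out = pd.DataFrame(cols, index=exp.intensities.index)
        _fmt(out).to_csv(matrix_path, sep="\t", index_label="probe_id")
    else:
        _fmt(exp.intensities).to_csv(matrix_path, sep="\t", index_label="probe_id")
        if detection_path is not None and exp.detection_p is not None:
            _fmt(exp.detection_p).to_csv(detection_path, sep="\t", index_label="probe_id")
    exp.sample_annot.to_csv(sample_sheet_path, sep="\t", index_label="sample_id")
    exp.probe_annot.to_csv(probe_annot_path, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Read a standard GMT file (name, description, member gene ids)."""
    sets: dict[str, frozenset[str]] = {}
    prov: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s), need >= 3"
                )
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            ndup = len(genes) - len(set(genes))
            if ndup:
                logger.info("read_gmt: set %s had %d duplicate id(s)", name, ndup)
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(genes)
            prov[name] = desc
    return GeneSetCollection(sets, prov)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            desc = collection.provenance.get(name, "")
            members = sorted(collection[name])
            fh.write("\t".join([name, desc, *members]) + "\n")
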