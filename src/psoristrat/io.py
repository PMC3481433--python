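"""File formats (GCT #1.2, CLS, GMT, TSV), domain containers and config.

The expression containers are deliberately thin: a validated matrix plus
ordered feature/sample identifiers, convertible to a pandas DataFrame.
Parsers preserve file order exactly and round-trip bit-identically.
"""

from __future__ import annotations

import dataclasses
import difflib
import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

TISSUE_CLASSES = ("NN", "PN", "PP")


class FormatError(ValueError):
    """A file violates its declared format."""


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values: rows = features, columns = samples."""

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    feature_level: str = "probe"
    descriptions: Optional[list[str]] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = list(self.feature_ids)
        self.sample_ids = list(self.sample_ids)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples")
        for name, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            seen, dups = set(), []
            for i in ids:
                if i in seen:
                    dups.append(i)
                seen.add(i)
            if dups:
                raise ValueError(f"duplicate {name} ids: {sorted(set(dups))}")
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must be finite (no NaN/inf)")
        if self.feature_level not in ("probe", "gene"):
            raise ValueError("feature_level must be 'probe' or 'gene'")

    @property
    def n_features(self):
        return len(self.feature_ids)

    @property
    def n_samples(self):
        return len(self.sample_ids)

    def to_frame(self):
        return pd.DataFrame(self.values, index=self.feature_ids,
                            columns=self.sample_ids)

    def subset(self, feature_ids=None, sample_ids=None):
        fi = self.feature_ids if feature_ids is None else list(feature_ids)
        si = self.sample_ids if sample_ids is None else list(sample_ids)
        fpos = {f: i for i, f in enumerate(self.feature_ids)}
        spos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [f for f in fi if f not in fpos] + [s for s in si if s not in spos]
        if missing:
            raise KeyError(f"unknown ids: {missing[:10]}")
        vals = self.values[np.ix_([fpos[f] for f in fi], [spos[s] for s in si])]
        return ExpressionMatrix(vals, fi, si, self.feature_level)


@dataclass
class SampleAnnotation:
    sample_id: str
    tissue_class: str
    subject_id: str
    clinical: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.tissue_class not in TISSUE_CLASSES:
            raise ValueError(f"unknown tissue class {self.tissue_class!r}")
        if self.tissue_class in ("PN", "PP") and not self.subject_id:
            raise ValueError(f"{self.sample_id}: PN/PP samples need a subject_id")


def validate_annotations(annotations):
    """Check the paired-cohort invariants: one PN and one PP per patient."""
    per_subject = {}
    for a in annotations:
        per_subject.setdefault(a.subject_id, []).append(a.tissue_class)
    for subj, classes in per_subject.items():
        for cls in ("PN", "PP"):
            if classes.count(cls) > 1:
                raise ValueError(f"subject {subj} has multiple {cls} samples")
        if "NN" in classes and set(classes) != {"NN"}:
            raise ValueError(f"control subject {subj} also has patient samples")


def annotations_to_frame(annotations):
    rows = []
    for a in annotations:
        row = {"sample_id": a.sample_id, "tissue_class": a.tissue_class,
               "subject_id": a.subject_id}
        row.update(a.clinical)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways) with free-text descriptions."""

    sets: dict  # name -> (description, frozenset of gene ids)

    def __post_init__(self):
        for name, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def members(self, name):
        return self.sets[name][1]

    def __len__(self):
        return len(self.sets)


# ---------------------------------------------------------------------------
# GCT / CLS / GMT / TSV

def parse_expression_gct(path):
    """Read a GenePattern GCT (#1.2) or plain TSV expression matrix."""
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("#"):
            fh.seek(0)
            return _parse_expression_tsv(fh, path)
        if first.strip() != "#1.2":
            raise FormatError(f"{path}: unsupported GCT version {first.strip()!r}; "
                              "only '#1.2' is accepted")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise FormatError(f"{path} line 2: expected '<rows>\\t<cols>'")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != 2 + n_cols:
            raise FormatError(f"{path} line 3: header declares {len(header) - 2} "
                              f"samples but line 2 declares {n_cols}")
        sample_ids = header[2:]
        feature_ids, descriptions, rows = [], [], []
        for ln, line in enumerate(fh, start=4):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 + n_cols:
                raise FormatError(f"{path} line {ln}: {len(parts) - 2} values, "
                                  f"expected {n_cols}")
            feature_ids.append(parts[0])
            descriptions.append(parts[1])
            try:
                rows.append([float(v) for v in parts[2:]])
            except ValueError as e:
                raise FormatError(f"{path} line {ln}: non-numeric value ({e})")
    if len(rows) != n_rows:
        raise FormatError(f"{path}: line 2 declares {n_rows} rows but body has "
                          f"{len(rows)}")
    dup = pd.Index(feature_ids)
    if dup.has_duplicates:
        raise FormatError(f"{path}: duplicate feature ids: "
                          f"{sorted(set(dup[dup.duplicated()]))}")
    return ExpressionMatrix(np.array(rows), feature_ids, sample_ids,
                            descriptions=descriptions)


def _parse_expression_tsv(fh, path):
    df = pd.read_csv(fh, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise FormatError(f"{path}: duplicate feature ids: {dups}")
    return ExpressionMatrix(df.to_numpy(dtype=float), [str(i) for i in df.index],
                            [str(c) for c in df.columns])


def write_expression_gct(matrix, path):
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{matrix.n_features}\t{matrix.n_samples}\n")
        fh.write("Name\tDescription\t" + "\t".join(matrix.sample_ids) + "\n")
        desc = matrix.descriptions or ["na"] * matrix.n_features
        for fid, d, row in zip(matrix.feature_ids, desc, matrix.values):
            fh.write(fid + "\t" + d + "\t" + "\t".join(repr(float(v)) for v in row)
                     + "\n")


def parse_class_labels_cls(path, sample_ids, vocabulary=TISSUE_CLASSES):
    """Read a CLS label file aligned to ``sample_ids`` (order preserved)."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise FormatError(f"{path}: a CLS file has 3 lines")
    n_declared = int(lines[0].split()[0])
    labels = lines[2].split()
    if len(labels) != n_declared:
        raise FormatError(f"{path}: header declares {n_declared} labels, body has "
                          f"{len(labels)}")
    if len(labels) != len(sample_ids):
        raise FormatError(f"{path}: {len(labels)} labels for {len(sample_ids)} samples")
    unknown = sorted({l for l in labels if l not in vocabulary})
    if unknown:
        raise FormatError(f"{path}: unknown class token(s) {unknown}; "
                          f"vocabulary is {list(vocabulary)}")
    return labels


def write_class_labels_cls(labels, path):
    classes = list(dict.fromkeys(labels))
    with open(path, "w") as fh:
        fh.write(f"{len(labels)} {len(classes)} 1\n")
        fh.write("# " + " ".join(classes) + "\n")
        fh.write(" ".join(labels) + "\n")


def parse_gene_sets_gmt(path):
    """Read a GMT gene-set collection (name, description, members...)."""
    sets = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path} line {ln}: GMT lines need "
                                  "name, description and >= 1 member")
            name, desc = parts[0], parts[1]
            if name in sets:
                raise FormatError(f"{path} line {ln}: duplicate set name {name!r}")
            members = frozenset(m for m in parts[2:] if m)
            if not members:
                raise FormatError(f"{path} line {ln}: set {name!r} has no members")
            sets[name] = (desc, members)
    return GeneSetCollection(sets)


def write_gene_sets_gmt(collection, path):
    with open(path, "w") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write(name + "\t" + desc + "\t" + "\t".join(sorted(members)) + "\n")


# ---------------------------------------------------------------------------
# Pipeline configuration

@dataclass
class PipelineConfig:
    """All pipeline tunables with their documented defaults."""

    de_alpha: float = 0.05
    de_fdr: float = 0.05
    de_top_k: int = 5000
    n_trees: int = 1000
    subsample_fraction: float = 2.0 / 3.0
    mtry: Optional[int] = None            # None -> floor(sqrt(p))
    n_permutations: int = 1000
    reference_mode: str = "marginal_permutation"
    dissimilarity_transform: str = "sqrt_one_minus"
    k_subgroups: int = 2
    corr_threshold: float = 0.80
    mcl_inflation: float = 2.0
    mcl_expansion: int = 2
    enrichment_universe_size: int = 20000
    min_cluster_size_for_enrichment: int = 9
    rng_seed: int = 0

    def __post_init__(self):
        def _check(cond, msg):
            if not cond:
                raise ValueError(msg)
        _check(0 < self.de_alpha <= 1, f"de_alpha must be in (0,1], got {self.de_alpha}")
        _check(0 < self.de_fdr <= 1, f"de_fdr must be in (0,1], got {self.de_fdr}")
        _check(self.de_top_k >= 1, f"de_top_k must be >= 1, got {self.de_top_k}")
        _check(self.n_trees >= 1, f"n_trees must be >= 1, got {self.n_trees}")
        _check(0 < self.subsample_fraction <= 1,
               f"subsample_fraction must be in (0,1], got {self.subsample_fraction}")
        _check(self.mtry is None or self.mtry >= 1, "mtry must be >= 1 or null")
        _check(self.n_permutations >= 1, "n_permutations must be >= 1")
        _check(self.reference_mode in ("marginal_permutation", "marginal_resample"),
               f"reference_mode: unknown mode {self.reference_mode!r}")
        _check(self.dissimilarity_transform in ("sqrt_one_minus", "one_minus"),
               f"dissimilarity_transform: unknown {self.dissimilarity_transform!r}")
        _check(self.k_subgroups >= 1, "k_subgroups must be >= 1")
        _check(0 <= self.corr_threshold <= 1,
               f"corr_threshold must be in [0,1], got {self.corr_threshold}")
        _check(self.mcl_inflation > 1, "mcl_inflation must be > 1")
        _check(self.mcl_expansion >= 2 and int(self.mcl_expansion) == self.mcl_expansion,
               "mcl_expansion must be an integer >= 2")
        _check(self.enrichment_universe_size >= 1,
               "enrichment_universe_size must be >= 1")
        _check(self.min_cluster_size_for_enrichment >= 1,
               "min_cluster_size_for_enrichment must be >= 1")

    def to_dict(self):
        return dataclasses.asdict(self)


def load_config(path=None, **overrides):
    """Resolve a :class:`PipelineConfig` from a YAML file plus overrides.

    Unknown keys are rejected (with a did-you-mean suggestion) rather than
    silently ignored; out-of-range values raise naming the key.
    """
    data = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        data.update(loaded or {})
    data.update(overrides)
    valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    for key in data:
        if key not in valid:
            hint = difflib.get_close_matches(key, valid, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"unknown config key {key!r}{suffix}")
    cfg = PipelineConfig(**data)
    log.info("resolved config: %s", cfg.to_dict())
    return cfg


def write_run_manifest(config, seed, out_path, extra=None):
    """Provenance record written next to every output directory."""
    import psoristrat
    manifest = {"config": config.to_dict(), "seed": seed,
                "versions": {"psoristrat": psoristrat.__version__,
                             "numpy": np.__version__,
                             "pandas": pd.__version__}}
    if extra:
        manifest.update(extra)
    with open(out_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
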