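"""Synthetic paired-design psoriasis cohorts with planted structure.

The generator emulates the study design every downstream stage assumes:
34 control subjects contributing one normal-skin sample (NN) each, and 37
patients contributing a paired non-lesional (PN) and lesional (PP) sample
that share a per-subject random effect. On top of a per-gene log2
baseline it plants

* class-level differential expression: a fixed-magnitude shift per DE
  gene (``pn_shift_sd`` noise-sd units in PN, ``pp_shift_sd`` in PP,
  same sign, ~63% of genes up-regulated), so lesional tissue is the most
  differentiated — normal, non-lesional and lesional form a gradient;
* a two-way molecular split of the patients: ``subgroup_genes`` extra
  genes shifted by ``subgroup_shift_sd`` only in the lesional samples of
  the PP02 subgroup;
* a clinical positive control: patient age offset by ``age_offset``
  years between the two planted subgroups.

Everything is a pure function of the seed; identical seeds give
bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io import ExpressionMatrix, SampleAnnotation

CLINICAL_VARIABLES = ("PASI", "BMI", "age_of_onset", "age", "BSA")


@dataclass
class CohortDesign:
    """Generator settings; defaults mirror the emulated cohort design.

    Shift parameters are effect magnitudes in units of ``noise_sd``.
    """

    n_controls: int = 34
    n_patients: int = 37
    n_genes: int = 1000
    baseline_mean_loc: float = 7.0
    baseline_mean_scale: float = 1.0
    noise_sd: float = 1.0
    subject_effect_sd: float = 0.5
    de_genes: int = 150
    pn_shift_sd: float = 0.5
    pp_shift_sd: float = 1.5
    up_fraction: float = 130.0 / 206.0
    subgroup_genes: int = 25
    subgroup_shift_sd: float = 2.0
    subgroup_proportion: float = 0.5
    age_offset: float = 10.0
    age_mean: float = 50.0
    age_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_controls < 1 or self.n_patients < 1 or self.n_genes < 1:
            raise ValueError("cohort sizes must be positive")
        if self.de_genes + self.subgroup_genes > self.n_genes:
            raise ValueError("de_genes + subgroup_genes must be <= n_genes")
        if not 0 < self.subgroup_proportion < 1:
            raise ValueError("subgroup_proportion must be in (0, 1)")
        if not 0 <= self.up_fraction <= 1:
            raise ValueError("up_fraction must be in [0, 1]")
        if self.noise_sd < 0 or self.subject_effect_sd < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass
class PlantedTruth:
    """Ground truth of a simulated cohort, for parameter-recovery checks."""

    de_gene_ids: list
    de_shifts: dict               # gene id -> {"pn": shift, "pp": shift}
    de_signs: dict                # gene id -> +1 / -1
    subgroup_gene_ids: list
    subgroup_shifts: dict         # gene id -> signed shift applied in PP02
    subgroup_labels: dict         # patient subject_id -> "PP01" / "PP02"
    seed: int = 0
    all_gene_ids: list = field(default_factory=list)


def generate_cohort(design: CohortDesign):
    """Simulate one cohort.

    Returns ``(ExpressionMatrix, [SampleAnnotation], PlantedTruth)``. The
    matrix has ``n_controls + 2 * n_patients`` columns; each patient's PN
    and PP columns share one subject effect, so with ``noise_sd = 0`` the
    PP-minus-PN difference per gene is exactly the planted class (plus
    subgroup) shift.
    """
    d = design
    rng = np.random.default_rng(d.seed)
    g = d.n_genes
    genes = [f"G{i + 1:04d}" for i in range(g)]

    # sample layout: controls first, then PN/PP pairs per patient
    subjects = [f"C{i + 1:02d}" for i in range(d.n_controls)] + \
               [f"P{i + 1:02d}" for i in range(d.n_patients)]
    sample_ids, classes, sample_subject = [], [], []
    for i in range(d.n_controls):
        sample_ids.append(f"NN_C{i + 1:02d}")
        classes.append("NN")
        sample_subject.append(f"C{i + 1:02d}")
    for i in range(d.n_patients):
        for cls in ("PN", "PP"):
            sample_ids.append(f"{cls}_P{i + 1:02d}")
            classes.append(cls)
            sample_subject.append(f"P{i + 1:02d}")
    n_samples = len(sample_ids)

    baseline = rng.normal(d.baseline_mean_loc, d.baseline_mean_scale, size=g)

    special = rng.choice(g, size=d.de_genes + d.subgroup_genes, replace=False)
    de_idx = np.sort(special[:d.de_genes])
    sub_idx = np.sort(special[d.de_genes:])

    n_up = int(round(d.up_fraction * d.de_genes))
    signs = np.full(d.de_genes, -1.0)
    signs[rng.permutation(d.de_genes)[:n_up]] = 1.0
    pn_shift = np.zeros(g)
    pp_shift = np.zeros(g)
    pn_shift[de_idx] = signs * d.pn_shift_sd * d.noise_sd
    pp_shift[de_idx] = signs * d.pp_shift_sd * d.noise_sd

    sub_signs = rng.choice([-1.0, 1.0], size=d.subgroup_genes)
    sub_shift = np.zeros(g)
    sub_shift[sub_idx] = sub_signs * d.subgroup_shift_sd * d.noise_sd

    n_pp02 = int(round(d.subgroup_proportion * d.n_patients))
    pp02_patients = set(rng.permutation(d.n_patients)[:n_pp02])
    subgroup_labels = {f"P{i + 1:02d}": ("PP02" if i in pp02_patients else "PP01")
                       for i in range(d.n_patients)}

    subj_eff = dict(zip(subjects,
                        rng.normal(0.0, d.subject_effect_sd, size=len(subjects))))

    X = np.empty((g, n_samples))
    noise = rng.normal(0.0, d.noise_sd, size=(g, n_samples))
    for s in range(n_samples):
        col = baseline + subj_eff[sample_subject[s]] + noise[:, s]
        if classes[s] == "PN":
            col = col + pn_shift
        elif classes[s] == "PP":
            col = col + pp_shift
            if subgroup_labels[sample_subject[s]] == "PP02":
                col = col + sub_shift
        X[:, s] = col

    ages = {subj: float(rng.normal(d.age_mean, d.age_sd)) for subj in subjects}
    for subj, lab in subgroup_labels.items():
        if lab == "PP02":
            ages[subj] += d.age_offset

    annotations = []
    for sid, cls, subj in zip(sample_ids, classes, sample_subject):
        clinical = {v: None for v in CLINICAL_VARIABLES}
        clinical["age"] = ages[subj]
        annotations.append(SampleAnnotation(sid, cls, subj, clinical))

    truth = PlantedTruth(
        de_gene_ids=[genes[i] for i in de_idx],
        de_shifts={genes[i]: {"pn": float(pn_shift[i]), "pp": float(pp_shift[i])}
                   for i in de_idx},
        de_signs={genes[i]: int(s) for i, s in zip(de_idx, signs)},
        subgroup_gene_ids=[genes[i] for i in sub_idx],
        subgroup_shifts={genes[i]: float(sub_shift[i]) for i in sub_idx},
        subgroup_labels=subgroup_labels,
        seed=d.seed,
        all_gene_ids=genes,
    )
    matrix = ExpressionMatrix(X, genes, sample_ids, feature_level="gene")
    return matrix, annotations, truth


def truth_report(truth: PlantedTruth, recovered_genes=None,
                 recovered_partition=None, contrast="NN_vs_PP"):
    """Precision/recall of recovered DE genes and ARI of recovered subgroups.

    ``contrast`` names the comparison the recovered set came from and
    fixes the planted reference: in the ``NN_vs_PP`` contrast the
    subgroup genes are genuinely differentially expressed (they are
    shifted in the PP02 half of the lesional samples), so they count as
    planted signal alongside the class-DE genes; ``class_de`` restricts
    the reference to the class-DE genes alone. ``recovered_partition``
    maps patient subject ids (or their PP sample ids ``PP_<subject>``)
    to cluster labels.
    """
    from .stratify import adjusted_rand_index

    out = {}
    if recovered_genes is not None:
        rec = set(getattr(recovered_genes, "genes", recovered_genes))
        known = set(truth.all_gene_ids) if truth.all_gene_ids else None
        if known is not None:
            unknown = sorted(rec - known)
            if unknown:
                raise KeyError(f"unknown gene ids: {unknown[:10]}")
        if contrast == "NN_vs_PP":
            planted = set(truth.de_gene_ids) | set(truth.subgroup_gene_ids)
        elif contrast == "class_de":
            planted = set(truth.de_gene_ids)
        else:
            raise ValueError(f"unknown contrast {contrast!r}")
        hits = len(rec & planted)
        out["precision"] = hits / len(rec) if rec else 0.0
        out["recall"] = hits / len(planted)
    if recovered_partition is not None:
        labels = dict(recovered_partition)
        norm = {}
        for key, lab in labels.items():
            subj = key.split("_", 1)[1] if "_" in str(key) else key
            norm[subj] = lab
        unknown = sorted(set(norm) - set(truth.subgroup_labels))
        if unknown:
            raise KeyError(f"unknown subject ids: {unknown[:10]}")
        subjects = sorted(norm)
        out["ari"] = adjusted_rand_index(
            [truth.subgroup_labels[s] for s in subjects],
            [norm[s] for s in subjects])
    return out
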