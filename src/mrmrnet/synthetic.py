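"""Synthetic two-group expression data with known ground truth.

Emulates a case/control lncRNA+mRNA microarray study (log2 intensities,
15 vs 15 samples by default) at desk scale, planting three kinds of
structure that the downstream stages must recover:

* **informative** features whose group means differ by a chosen effect
  size (the mRMR relevance signal),
* **redundant** features that are noisy copies of informative ones
  (the mRMR redundancy penalty target), and
* **co-expressed lncRNA-mRNA pairs** sharing a latent factor at a chosen
  Pearson correlation (the network-recovery signal).

Everything is driven by one integer seed; identical config + seed gives
bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import AnnotationCollection, ExpressionMatrix, ValidationError


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters for the generator.

    Defaults mirror a 15 + 15 case/control microarray design with 2,000
    probes, a 2 log2-unit group shift on informative features, unit
    residual noise, and lncRNA-mRNA pairs planted at r = 0.9.
    """

    n_case: int = 15
    n_control: int = 15
    n_informative: int = 20
    n_redundant: int = 20
    n_noise: int = 1960
    n_coexpressed: int = 20          # planted lncRNA-mRNA pairs (within n_noise)
    n_lnc_fraction: float = 0.54     # lncRNA share of probes on the array
    effect_size: float = 2.0         # log2-units between group means
    within_correlation: float = 0.9  # target Pearson r of planted pairs
    noise_sd: float = 1.0            # log2-units residual sd
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_informative, self.n_redundant, self.n_noise,
                  self.n_coexpressed)
        if any(c < 0 for c in counts):
            raise ValidationError("feature counts must be >= 0")
        if self.n_case < 2 or self.n_control < 2:
            raise ValidationError("need >= 2 samples per group")
        if self.n_case + self.n_control < 4:
            raise ValidationError("need >= 4 samples in total")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        if not 0.0 <= self.within_correlation <= 1.0:
            raise ValidationError("within_correlation must be in [0, 1]")
        if not 0.0 <= self.n_lnc_fraction <= 1.0:
            raise ValidationError("n_lnc_fraction must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if 2 * self.n_coexpressed > self.n_noise:
            raise ValidationError("n_coexpressed pairs exceed available noise features")

    @property
    def n_features(self) -> int:
        return self.n_informative + self.n_redundant + self.n_noise

    @property
    def n_samples(self) -> int:
        return self.n_case + self.n_control


@dataclass
class GroundTruth:
    """What was planted, keyed by the generated feature ids."""

    informative_ids: set
    redundant_pairs: list          # (source_id, copy_id)
    coexpressed_pairs: list        # (lnc_id, mrna_id, planted_r)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "informative_ids": sorted(self.informative_ids),
            "redundant_pairs": [list(p) for p in self.redundant_pairs],
            "coexpressed_pairs": [[a, b, r] for a, b, r in self.coexpressed_pairs],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(set(d["informative_ids"]),
                   [tuple(p) for p in d["redundant_pairs"]],
                   [tuple(p) for p in d["coexpressed_pairs"]])


BASELINE_MEAN = 8.0   # log2 intensity of a typical probe
BASELINE_SD = 1.5     # spread of probe baselines
COPY_NOISE_FACTOR = 0.2  # perturbation sd of redundant copies, x noise_sd


def generate_expression(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, pd.Series, GroundTruth]:
    """Generate an expression matrix, class labels and the ground truth.

    Returns
    -------
    matrix, labels, truth
        ``matrix`` has ``config.n_features`` rows and
        ``config.n_samples`` columns; ``labels`` maps sample id to
        ``case``/``control``.
    """
    rng = np.random.default_rng(config.seed)
    nf, ns = config.n_features, config.n_samples
    case = np.arange(ns) < config.n_case

    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=nf)
    values = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(nf, ns))

    # roles are scattered over row positions so feature order carries no signal
    order = rng.permutation(nf)
    ni, nr = config.n_informative, config.n_redundant
    informative_idx = order[:ni]
    redundant_idx = order[ni:ni + nr]
    noise_idx = order[ni + nr:]

    # informative: opposite half-shifts so |mean(case) - mean(control)| = effect
    signs = rng.choice([-1.0, 1.0], size=ni)
    shift = signs * config.effect_size / 2.0
    values[np.ix_(informative_idx, np.where(case)[0])] += shift[:, None]
    values[np.ix_(informative_idx, np.where(~case)[0])] -= shift[:, None]

    # redundant: noisy copies of informative sources (noise sources if ni = 0)
    source_pool = informative_idx if ni > 0 else noise_idx
    if nr > 0 and len(source_pool) == 0:
        raise ValidationError("redundant features need informative or noise sources")
    copy_sd = COPY_NOISE_FACTOR * config.noise_sd
    source_idx = source_pool[np.arange(nr) % len(source_pool)] if nr else np.array([], int)
    for src, dst in zip(source_idx, redundant_idx):
        values[dst] = values[src] + rng.normal(0.0, copy_sd, size=ns)

    # co-expressed lncRNA-mRNA pairs share a latent factor; with
    # x = sqrt(w) z + sqrt(1-w) e the pair correlation is w.
    rho = config.within_correlation
    biotype_is_lnc = rng.random(nf) < config.n_lnc_fraction
    lnc_noise = [i for i in noise_idx if biotype_is_lnc[i]]
    mrna_noise = [i for i in noise_idx if not biotype_is_lnc[i]]
    if config.n_coexpressed > min(len(lnc_noise), len(mrna_noise)):
        raise ValidationError(
            "not enough noise features of each biotype for the requested "
            "number of co-expressed pairs"
        )
    pair_idx = list(zip(lnc_noise[: config.n_coexpressed],
                        mrna_noise[: config.n_coexpressed]))
    w_lat, w_res = np.sqrt(rho), np.sqrt(1.0 - rho)
    for a, b in pair_idx:
        z = rng.normal(0.0, 1.0, size=ns)
        for i in (a, b):
            resid = rng.normal(0.0, 1.0, size=ns)
            values[i] = baseline[i] + config.noise_sd * (w_lat * z + w_res * resid)

    # ids numbered within biotype, in row order
    feature_ids = np.empty(nf, dtype=object)
    n_lnc = n_mrna = 0
    for i in range(nf):
        if biotype_is_lnc[i]:
            n_lnc += 1
            feature_ids[i] = f"LNC_{n_lnc:04d}"
        else:
            n_mrna += 1
            feature_ids[i] = f"MRNA_{n_mrna:04d}"

    sample_ids = [f"CASE_{i + 1:02d}" for i in range(config.n_case)] + \
                 [f"CTRL_{i + 1:02d}" for i in range(config.n_control)]
    df = pd.DataFrame(values, index=pd.Index(feature_ids, name="feature_id"),
                      columns=sample_ids)
    biotype = pd.Series(np.where(biotype_is_lnc, "lncRNA", "mRNA"),
                        index=df.index, name="biotype")
    labels = pd.Series(np.where(case, "case", "control"), index=df.columns,
                       name="class")

    truth = GroundTruth(
        informative_ids=set(feature_ids[informative_idx]),
        redundant_pairs=[(feature_ids[s], feature_ids[d])
                         for s, d in zip(source_idx, redundant_idx)],
        coexpressed_pairs=[(feature_ids[a], feature_ids[b], rho)
                           for a, b in pair_idx],
    )
    return ExpressionMatrix(df, biotype), labels, truth


def generate_annotations(
    matrix: ExpressionMatrix,
    informative_ids: set,
    n_categories: int,
    enriched_category_fraction: float,
    seed: int,
    size_range: tuple[int, int] = (10, 40),
    informative_member_fraction: float = 0.6,
) -> tuple[AnnotationCollection, list[str]]:
    """Generate a gene-set collection with planted-enriched categories.

    ``enriched_category_fraction`` of the ``n_categories`` categories draw
    ``informative_member_fraction`` of their members from
    *informative_ids*; the rest are uniform draws from the matrix's
    feature universe.  Returns the collection and the planted category ids.
    """
    if n_categories < 1:
        raise ValidationError("n_categories must be >= 1")
    if not 0.0 <= enriched_category_fraction <= 1.0:
        raise ValidationError("enriched_category_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    universe = list(matrix.feature_ids)
    if size_range[1] > len(universe):
        raise ValidationError("category size exceeds universe size")
    informative = sorted(set(informative_ids) & set(universe))

    n_enriched = int(round(enriched_category_fraction * n_categories))
    categories: dict[str, tuple[str, frozenset]] = {}
    planted: list[str] = []
    for k in range(n_categories):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        cid = f"CAT_{k + 1:04d}"
        if k < n_enriched and informative:
            n_inf = min(int(round(informative_member_fraction * size)),
                        len(informative))
            inf_members = list(rng.choice(informative, size=n_inf, replace=False))
            rest_pool = [f for f in universe if f not in set(inf_members)]
            rest = list(rng.choice(rest_pool, size=size - n_inf, replace=False))
            members = frozenset(inf_members + rest)
            planted.append(cid)
            desc = "planted enriched category"
        else:
            members = frozenset(rng.choice(universe, size=size, replace=False))
            desc = "random category"
        categories[cid] = (desc, members)
    return AnnotationCollection(categories, frozenset(universe)), planted


def generate_ct_table(
    n_targets: int,
    n_samples_per_group: int,
    planted_fold_changes: list[float],
    ref_ct: float = 18.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    target_base_ct: float = 26.0,
    reference_gene: str = "ACTB",
):
    """Generate a qPCR Ct table with planted case/control fold changes.

    A fold change F > 1 means higher expression in cases, i.e. the target
    amplifies ``log2(F)`` cycles *earlier* in cases.  The reference gene
    has the same expected Ct in both groups.  With ``noise_sd = 0`` the
    downstream 2^-ddCt computation recovers each planted fold exactly.

    Returns a :class:`mrmrnet.diffexpr.CtTable`.
    """
    from .diffexpr import CtTable  # local import avoids a cycle

    folds = np.asarray(planted_fold_changes, dtype=float)
    if len(folds) != n_targets:
        raise ValidationError("need one planted fold change per target")
    if np.any(folds <= 0):
        raise ValidationError("planted fold changes must be > 0")
    if not 10.0 <= ref_ct <= 35.0:
        raise ValidationError("ref_ct outside the plausible 10-35 cycle range")
    rng = np.random.default_rng(seed)
    n = 2 * n_samples_per_group
    case = np.arange(n) < n_samples_per_group

    genes = [f"TARGET_{i + 1:02d}" for i in range(n_targets)] + [reference_gene]
    samples = [f"CASE_{i + 1:02d}" for i in range(n_samples_per_group)] + \
              [f"CTRL_{i + 1:02d}" for i in range(n_samples_per_group)]
    ct = np.empty((n_targets + 1, n))
    for g in range(n_targets):
        base = np.full(n, target_base_ct)
        base[case] -= np.log2(folds[g])
        ct[g] = base + rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else base
    ct[-1] = ref_ct + (rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0)

    df = pd.DataFrame(ct, index=pd.Index(genes, name="gene"), columns=samples)
    classes = pd.Series(np.where(case, "case", "control"), index=samples,
                        name="class")
    return CtTable(df, reference_gene, classes)


def write_dataset(matrix: ExpressionMatrix, labels: pd.Series,
                  truth: GroundTruth, outdir: str | Path,
                  prefix: str = "synthetic") -> dict[str, Path]:
    """Write matrix/labels/biotypes TSVs and the ground-truth JSON sidecar."""
    from .io import write_biotypes, write_labels, write_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / f"{prefix}.matrix.tsv",
        "labels": outdir / f"{prefix}.labels.tsv",
        "biotypes": outdir / f"{prefix}.biotypes.tsv",
        "truth": outdir / f"{prefix}.truth.json",
    }
    write_matrix(matrix, paths["matrix"])
    write_labels(labels, paths["labels"])
    write_biotypes(matrix.biotype, paths["biotypes"])
    truth.to_json(paths["truth"])
    return paths
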