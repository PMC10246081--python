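"""Synthetic cohorts and phenotype-conditioned FC generation.

Two roles:

1. ``generate_cohort`` builds a multi-subject, multi-scan cohort of FC
   matrices with known ground truth, emulating the structure of real
   developmental/clinical fMRI cohorts: every subject has an angle basis
   (population template + phenotype effects + subject-level variation), a
   stable subject-unique residual signature that repeats across scans, and
   fresh scan noise.  This is the stated world every other module is tested
   against.

2. ``train_phenotype_models`` + ``synthesize_fc`` implement generation of
   new FC conditioned on phenotype targets: a set of frozen linear critics
   (one bag of 20 per phenotype, trained on vectorized FC) scores candidate
   matrices, and projected gradient descent on angle-basis parameters moves a
   random initial basis until the critics' average prediction matches the
   requested phenotype record.  Different seeds give different matrices with
   the same achieved predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, Ridge

from .core import TWO_PI, AngleBasis, FCMatrix, reconstruct, vectorize

__all__ = [
    "PhenotypeEffect",
    "CohortSpec",
    "SyntheticCohort",
    "FrozenLinearModel",
    "generate_cohort",
    "train_phenotype_models",
    "synthesize_fc",
]


@dataclass(frozen=True)
class PhenotypeEffect:
    """A phenotype-linked shift of basis parameters on a region set.

    For a categorical phenotype the effect applies to subjects whose label
    equals ``value``; for ``phenotype == "age"`` the effect is continuous and
    scales with the subject's z-scored age.
    """

    phenotype: str
    value: object | None
    regions: tuple[int, ...]
    phase_shift: float = 0.0
    jitter_delta: float = 0.0


def default_effects(n_regions: int) -> tuple[PhenotypeEffect, ...]:
    """Moderate, literature-shaped default effects on block structure.

    The first block plays the role of the default-mode network: females get
    stronger within-block connectivity (higher jitter), schizophrenia lower;
    ancestry and age modulate other blocks.  Magnitudes are moderate (0.1-0.15
    jitter, 0.2-0.3 rad) so effects are learnable but far from separable by a
    single edge.
    """
    q = n_regions // 4
    b0 = tuple(range(0, q))
    b1 = tuple(range(q, 2 * q))
    b2 = tuple(range(2 * q, 3 * q))
    return (
        PhenotypeEffect("sex", "F", b0, jitter_delta=0.15),
        PhenotypeEffect("diagnosis", "SZ", b0, jitter_delta=-0.15),
        PhenotypeEffect("race", "EA", b2, phase_shift=0.25, jitter_delta=0.10),
        PhenotypeEffect("age", None, b1, phase_shift=0.30),
    )


@dataclass(frozen=True)
class CohortSpec:
    """Declarative description of a synthetic cohort.

    Defaults mirror a desk-scale developmental cohort: 50 subjects with 3
    scans each (three in-scanner tasks), ages 8-22, two ancestry groups, a
    minority schizophrenia-like diagnosis.  Each scan perturbs the subject's
    basis (``scan_phase_sd``/``scan_jitter_sd``): different in-scanner tasks
    put the brain in different large-scale phase configurations, which is why
    raw-FC fingerprinting across tasks is hard, while the residual signature
    (stable across a subject's scans, sd ``subject_signature_strength``)
    survives the decomposition and fingerprints well.
    """

    n_subjects: int = 50
    scans_per_subject: int = 3
    n_regions: int = 50
    phenotype_effects: tuple[PhenotypeEffect, ...] | None = None
    subject_signature_strength: float = 0.04
    scan_noise_sd: float = 0.05
    subject_phase_sd: float = 0.04
    subject_jitter_sd: float = 0.02
    scan_phase_sd: float = 0.15
    scan_jitter_sd: float = 0.05
    sz_fraction: float = 0.3
    age_range: tuple[float, float] = (8.0, 22.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1 or self.scans_per_subject < 1 or self.n_regions < 4:
            raise ValueError("cohort must have subjects, scans and >= 4 regions")
        for name in ("subject_signature_strength", "scan_noise_sd",
                     "subject_phase_sd", "subject_jitter_sd",
                     "scan_phase_sd", "scan_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        effects = self.phenotype_effects
        if effects is None:
            effects = default_effects(self.n_regions)
        for eff in effects:
            if any(r < 0 or r >= self.n_regions for r in eff.regions):
                raise ValueError(
                    f"effect on {eff.phenotype!r} references regions outside "
                    f"[0, {self.n_regions})"
                )
        object.__setattr__(self, "phenotype_effects", tuple(effects))


@dataclass(frozen=True)
class SyntheticCohort:
    """FC matrices (one per phenotype-table row) plus full ground truth."""

    fc_matrices: list[FCMatrix]
    phenotypes: pd.DataFrame
    subject_bases: dict
    subject_signatures: dict
    spec: CohortSpec

    def features(self) -> np.ndarray:
        """Scans x R(R-1)/2 matrix of vectorized FC."""
        return np.stack([vectorize(fc.values) for fc in self.fc_matrices])


def _population_template(n_regions, rng):
    """Blocky template basis: 4 phase-clustered blocks, first block strongest."""
    q, rem = divmod(n_regions, 4)
    sizes = [q + (1 if i < rem else 0) for i in range(4)]
    centers = np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])
    jitter_levels = np.array([0.9, 0.7, 0.7, 0.6])
    phases = np.concatenate(
        [centers[i] + 0.2 * rng.standard_normal(sizes[i]) for i in range(4)]
    )
    jitters = np.concatenate([np.full(sizes[i], jitter_levels[i]) for i in range(4)])
    return phases % TWO_PI, jitters


def _symmetric_noise(n, sd, rng):
    a = rng.standard_normal((n, n)) * sd
    out = (a + a.T) / np.sqrt(2.0)  # entries keep standard deviation sd
    np.fill_diagonal(out, 0.0)
    return out


def _assemble_fc(matrix):
    m = 0.5 * (matrix + matrix.T)
    np.clip(m, -1.0, 1.0, out=m)
    np.fill_diagonal(m, 1.0)
    return FCMatrix(m)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a full cohort. Deterministic given ``spec.seed``."""
    root = np.random.default_rng(np.random.SeedSequence(spec.seed))
    template_rng, pheno_rng, subject_rng, scan_rng = (
        np.random.default_rng(s) for s in np.random.SeedSequence(spec.seed).spawn(4)
    )
    del root
    r = spec.n_regions
    tpl_phase, tpl_jit = _population_template(r, template_rng)

    lo, hi = spec.age_range
    ages = pheno_rng.uniform(lo, hi, spec.n_subjects)
    age_mu, age_sd = ages.mean(), max(ages.std(), 1e-9)
    sexes = pheno_rng.choice(["F", "M"], spec.n_subjects)
    races = pheno_rng.choice(["AA", "EA"], spec.n_subjects)
    dx = np.where(pheno_rng.random(spec.n_subjects) < spec.sz_fraction, "SZ", "NC")

    rows = []
    fcs: list[FCMatrix] = []
    bases: dict = {}
    signatures: dict = {}
    for s in range(spec.n_subjects):
        subject_id = f"sub-{s:04d}"
        phases = tpl_phase + spec.subject_phase_sd * subject_rng.standard_normal(r)
        jitters = tpl_jit + spec.subject_jitter_sd * subject_rng.standard_normal(r)
        labels = {"sex": sexes[s], "race": races[s], "diagnosis": dx[s]}
        for eff in spec.phenotype_effects:
            idx = np.asarray(eff.regions, dtype=int)
            if eff.phenotype == "age":
                scale = (ages[s] - age_mu) / age_sd
            else:
                scale = 1.0 if labels[eff.phenotype] == eff.value else 0.0
            phases[idx] += scale * eff.phase_shift
            jitters[idx] += scale * eff.jitter_delta
        basis = AngleBasis(
            phases=(phases % TWO_PI)[None, :],
            jitters=np.clip(jitters, 0.0, 1.0)[None, :],
        )
        signature = _symmetric_noise(r, spec.subject_signature_strength, subject_rng)
        bases[subject_id] = basis
        signatures[subject_id] = signature
        for k in range(spec.scans_per_subject):
            # per-scan state/task perturbation of the subject's basis
            scan_phases = (
                basis.phases[0] + spec.scan_phase_sd * scan_rng.standard_normal(r)
            ) % TWO_PI
            scan_jitters = np.clip(
                basis.jitters[0] + spec.scan_jitter_sd * scan_rng.standard_normal(r),
                0.0,
                1.0,
            )
            recon = reconstruct(
                AngleBasis(phases=scan_phases[None, :], jitters=scan_jitters[None, :])
            )
            noise = _symmetric_noise(r, spec.scan_noise_sd, scan_rng)
            fcs.append(_assemble_fc(recon + signature + noise))
            rows.append(
                {
                    "subject_id": subject_id,
                    "scan_id": f"task-{k}",
                    "age": float(ages[s]),
                    "sex": sexes[s],
                    "race": races[s],
                    "diagnosis": dx[s],
                }
            )
    return SyntheticCohort(
        fc_matrices=fcs,
        phenotypes=pd.DataFrame(rows),
        subject_bases=bases,
        subject_signatures=signatures,
        spec=spec,
    )


@dataclass(frozen=True)
class FrozenLinearModel:
    """Read-only linear critic: continuous output w @ v + b (+ center for age)."""

    phenotype: str
    task: str
    coef: np.ndarray
    intercept: float
    center: float = 0.0
    classes: tuple | None = None  # (negative_label, positive_label)

    def __post_init__(self):
        coef = np.asarray(self.coef, dtype=float).copy()
        coef.flags.writeable = False
        object.__setattr__(self, "coef", coef)

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Decision score (classification) or target-scale prediction (regression)."""
        v = np.atleast_2d(np.asarray(features, dtype=float))
        return v @ self.coef + self.intercept + self.center


@dataclass(frozen=True)
class FrozenModelSet:
    """Critic bags plus the training-cohort summaries synthesis needs.

    ``class_targets[p][label]`` is the class-conditional mean of the bag's
    average decision score on the training cohort -- the score a typical
    member of that class actually attains, used as the synthesis target
    (a fixed +-1 target is far inside the decision boundary and does not
    survive transfer to held-out critics).  ``feature_mean`` anchors the
    synthesized FC to the population's connectivity profile.
    """

    critics: dict[str, list[FrozenLinearModel]]
    feature_mean: np.ndarray
    feature_scale: float
    class_targets: dict[str, dict]
    prediction_scales: dict[str, float]

    def __getitem__(self, pheno):
        return self.critics[pheno]

    def __contains__(self, pheno):
        return pheno in self.critics


def train_phenotype_models(
    cohort: SyntheticCohort,
    phenotypes: tuple[str, ...] = ("age", "sex", "race", "diagnosis"),
    n_models: int = 20,
    seed: int = 0,
) -> FrozenModelSet:
    """Bags of frozen linear critics trained on bootstrap resamples of the cohort."""
    table = cohort.phenotypes
    missing = [p for p in phenotypes if p not in table.columns]
    if missing:
        raise ValueError(f"cohort lacks phenotype column(s) {missing}")
    x = cohort.features()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    m = x.shape[0]
    out: dict[str, list[FrozenLinearModel]] = {}
    for pheno in phenotypes:
        y_raw = table[pheno].to_numpy()
        models = []
        for _ in range(n_models):
            for _ in range(1000):
                idx = rng.integers(0, m, size=m)  # bootstrap resample
                if pheno == "age" or len(np.unique(y_raw[idx])) == 2:
                    break
            else:
                raise ValueError(f"could not resample both classes for {pheno!r}")
            if pheno == "age":
                y = y_raw[idx].astype(float)
                center = y.mean()
                reg = Ridge(alpha=1.0)
                reg.fit(x[idx], y - center)
                models.append(
                    FrozenLinearModel(
                        phenotype=pheno,
                        task="regression",
                        coef=reg.coef_.copy(),
                        intercept=float(reg.intercept_),
                        center=float(center),
                    )
                )
            else:
                classes = tuple(sorted(np.unique(y_raw).tolist()))
                if len(classes) != 2:
                    raise ValueError(f"{pheno!r} is not binary: {classes}")
                y = (y_raw[idx] == classes[1]).astype(int)
                clf = LogisticRegression(C=1.0, max_iter=1000)
                clf.fit(x[idx], y)
                models.append(
                    FrozenLinearModel(
                        phenotype=pheno,
                        task="classification",
                        coef=clf.coef_.ravel().copy(),
                        intercept=float(clf.intercept_[0]),
                        classes=classes,
                    )
                )
        out[pheno] = models

    class_targets: dict[str, dict] = {}
    prediction_scales: dict[str, float] = {}
    for pheno, bag in out.items():
        scores = np.mean([m.predict(x) for m in bag], axis=0)
        y_raw = table[pheno].to_numpy()
        if bag[0].task == "classification":
            class_targets[pheno] = {
                label: float(scores[y_raw == label].mean()) for label in bag[0].classes
            }
            prediction_scales[pheno] = max(float(scores.std()), 1e-6)
        else:
            class_targets[pheno] = {}
            prediction_scales[pheno] = max(float(y_raw.astype(float).std()), 1e-6)
    return FrozenModelSet(
        critics=out,
        feature_mean=x.mean(axis=0),
        feature_scale=max(float(x.std()), 1e-6),
        class_targets=class_targets,
        prediction_scales=prediction_scales,
    )


def _critic_targets(models: FrozenModelSet, target):
    """Map a phenotype record to numeric critic score targets and scales.

    A classification request targets the class-conditional mean decision
    score the critics assign to real members of that class on their training
    cohort; a regression request targets the value itself.  Discrepancies are
    normalized by the bag's training-score (or target) spread so phenotypes
    on different scales are weighted comparably.
    """
    entries = []
    for pheno, value in target.items():
        if pheno not in models:
            raise ValueError(f"no trained critics for phenotype {pheno!r}")
        bag = models[pheno]
        if bag[0].task == "classification":
            classes = bag[0].classes
            if value not in classes:
                raise ValueError(f"{pheno!r} must be one of {classes}, got {value!r}")
            t = models.class_targets[pheno][value]
        else:
            t = float(value)
        entries.append((pheno, bag, t, models.prediction_scales[pheno]))
    return entries


def synthesize_fc(
    models: FrozenModelSet,
    target: dict,
    n_bases: int = 1,
    steps: int = 800,
    seed: int = 0,
    step_size: float = 0.05,
    anchor_weight: float = 1.0,
):
    """Generate one synthetic FC matrix matching a phenotype record.

    Starts from a seeded random angle basis and runs projected gradient
    descent on phases and jitters, minimizing

        mean_p ((critic-bag mean prediction - target_p) / scale_p)^2
        + anchor_weight * mean(((v - v_bar) / s)^2)

    where v is the vectorized reconstruction, v_bar the training cohort's
    mean feature vector and s its feature scale.  The anchor keeps the
    synthetic matrix inside the population's connectivity regime (a bare
    critic objective controls only a handful of linear directions and leaves
    the rest of the matrix at its random initialization, which transfers
    poorly to independent critics).  Steps are sup-norm normalized so
    progress is robust to critic weight scale.  Returns ``(FCMatrix,
    achieved)`` with the critics' final average prediction per phenotype.
    """
    entries = _critic_targets(models, target)
    if not entries:
        raise ValueError("empty phenotype target")
    n_features = len(models.feature_mean)
    n_regions = int(round((1 + np.sqrt(1 + 8 * n_features)) / 2))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    theta = rng.uniform(0.0, TWO_PI, (n_bases, n_regions))
    jit = np.ones((n_bases, n_regions))
    iu = np.triu_indices(n_regions, k=1)
    warmup = steps // 4  # phases organize before jitters may move (see fitting)

    mean_coefs = [np.mean([m.coef for m in bag], axis=0) for _, bag, _, _ in entries]
    mean_inter = [
        np.mean([m.intercept + m.center for m in bag]) for _, bag, _, _ in entries
    ]
    targets = np.array([t for _, _, t, _ in entries])
    scales = np.array([s for _, _, _, s in entries])
    v_bar = models.feature_mean
    fscale = models.feature_scale

    best = None
    for step in range(steps):
        # cosine-decayed sup-norm step: coarse moves early, refinement late
        eta = step_size * 0.5 * (1.0 + np.cos(np.pi * step / steps))
        diff = theta[:, :, None] - theta[:, None, :]
        cosd = np.cos(diff)
        sind = np.sin(diff)
        jprod = jit[:, :, None] * jit[:, None, :]
        recon = (jprod * cosd).mean(axis=0)
        v = recon[iu]
        preds = np.array([w @ v + b for w, b in zip(mean_coefs, mean_inter)])
        resid = (preds - targets) / scales
        anchor = (v - v_bar) / fscale
        objective = float(np.mean(resid**2) + anchor_weight * np.mean(anchor**2))
        if best is None or objective < best[0]:
            best = (objective, theta.copy(), jit.copy(), preds.copy())
        # dJ/dv, spread back to a symmetric ordered-pair derivative matrix
        dv = (2.0 * anchor_weight / (n_features * fscale)) * anchor
        for k, w in enumerate(mean_coefs):
            dv = dv + (2.0 / len(entries)) * resid[k] / scales[k] * w
        d_mat = np.zeros((n_regions, n_regions))
        d_mat[iu] = dv
        d_mat = 0.5 * (d_mat + d_mat.T)  # each ordered entry carries half
        grad_theta = -(2.0 / n_bases) * np.einsum("cd,ncd->nc", d_mat, jprod * sind)
        grad_j = (2.0 / n_bases) * np.einsum("cd,nd,ncd->nc", d_mat, jit, cosd)
        gmax = max(np.abs(grad_theta).max(), np.abs(grad_j).max(), 1e-12)
        theta = (theta - eta * grad_theta / gmax) % TWO_PI
        if step >= warmup:
            jit = np.clip(jit - eta * grad_j / gmax, 0.0, 1.0)

    _, theta, jit, preds = best
    basis = AngleBasis(phases=theta, jitters=jit)
    recon = reconstruct(basis)
    fc = _assemble_fc(recon)
    achieved = {pheno: float(p) for (pheno, _, _, _), p in zip(entries, preds)}
    if not np.all(np.isfinite(list(achieved.values()))):
        raise FloatingPointError("non-finite critic predictions during synthesis")
    return fc, achieved
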