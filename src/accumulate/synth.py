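"""Synthetic study generator: cohorts, trial data, and criterion scores.

A cohort is generated from latent individual differences in efficiency
(EEA) and speed (SEA) of evidence accumulation, plus caution (threshold
gap B), nondecision time and go-failure propensity, drawn from a
multivariate normal over subjects.  Latent traits map to LBA rates by the
exact inverse of the EEA/SEA definitions,

    v_match[c]    = SEA + EEA / 2 + match offset for condition c,
    v_mismatch[c] = SEA - EEA / 2 + mismatch offset for condition c,

with zero-mean condition offsets, so that the condition-averaged EEA/SEA
of the generating parameters equal the latent traits exactly and parameter
recovery closes the loop.  Criterion scores load on standardized latent
EEA with family- and site-level intercepts plus noise, emulating
cognitive-battery composites collected in nested cohort studies.

Default cohort sizes (40 subjects, 300 trials per n-back condition) keep a
full pipeline run fast; the ``paper_scale_lite`` preset (200 subjects)
supports fuller checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .ddm import DDMParams
from .lba import LBAParams, lba_simulate
from .tasks import TaskDesign, get_task
from .trial_data import SubjectDataset

#: zero-mean condition offsets on the match/mismatch rates: lures are the
#: hard discrimination in n-back; hard numerosity ratios lower both margins
RATE_OFFSETS = {
    "nback": {
        "match": {"target": 0.2, "lure": -0.4, "novel": 0.2},
        "mismatch": {"target": -0.2, "lure": 0.2, "novel": 0.0},
    },
    "numerosity": {
        "match": {"many_easy": 0.4, "few_easy": 0.4,
                  "many_hard": -0.4, "few_hard": -0.4},
        "mismatch": {"many_easy": -0.3, "few_easy": -0.3,
                     "many_hard": 0.3, "few_hard": 0.3},
    },
}

LATENTS = ("EEA", "SEA", "B", "t0", "pgf_logit")


@dataclass
class CriterionSpec:
    """One criterion score: loading on standardized latent EEA plus noise."""

    name: str
    loading: float = 0.45
    family_sd: float = 0.3
    site_sd: float = 0.2
    noise_sd: float = 0.825


@dataclass
class PopulationSpec:
    """Generative description of a synthetic cohort."""

    n_subjects: int = 40
    task: str = "nback"
    trials_per_condition: int = 300
    #: latent means in LATENTS order (EEA, SEA, B, t0, logit p_gf)
    latent_means: tuple = (1.5, 1.75, 0.9, 0.3, -3.5)
    latent_sds: tuple = (0.5, 0.4, 0.15, 0.05, 0.4)
    #: latent correlation matrix (positive definite), LATENTS order
    latent_corr: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [1.0, 0.3, 0.0, 0.0, 0.0],
                [0.3, 1.0, 0.0, 0.0, 0.0],
                [0.0, 0.0, 1.0, 0.0, 0.0],
                [0.0, 0.0, 0.0, 1.0, 0.0],
                [0.0, 0.0, 0.0, 0.0, 1.0],
            ]
        )
    )
    A: float = 0.5
    sv_mismatch: float = 1.0
    criteria: tuple = (
        CriterionSpec("total_cognition", 0.45),
        CriterionSpec("working_memory", 0.30),
        CriterionSpec("flexibility", 0.25),
        CriterionSpec("inhibition", 0.20),
    )
    n_families: int | None = None  # default: 2 subjects per family
    n_sites: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        corr = np.asarray(self.latent_corr, dtype=float)
        if corr.shape != (len(LATENTS), len(LATENTS)):
            raise ValueError(f"latent_corr must be {len(LATENTS)}x{len(LATENTS)}")
        if not np.allclose(corr, corr.T):
            raise ValueError("latent_corr must be symmetric")
        if np.min(np.linalg.eigvalsh(corr)) <= 0:
            raise ValueError("latent_corr must be positive definite")
        if any(sd < 0 for sd in self.latent_sds):
            raise ValueError("latent SDs must be >= 0")
        if self.trials_per_condition < 1:
            raise ValueError("trials per condition must be >= 1")

    @property
    def design(self) -> TaskDesign:
        return get_task(self.task)


def paper_scale_lite(**overrides) -> PopulationSpec:
    """Larger preset (200 subjects) for fuller checks."""
    overrides.setdefault("n_subjects", 200)
    return PopulationSpec(**overrides)


def rates_from_traits(eea: float, sea: float, task: str = "nback"
                      ) -> tuple[dict, dict]:
    """Inverse EEA/SEA map to per-condition match/mismatch rates."""
    offs = RATE_OFFSETS[get_task(task).name]
    v_match = {c: sea + eea / 2.0 + o for c, o in offs["match"].items()}
    v_mismatch = {c: sea - eea / 2.0 + o for c, o in offs["mismatch"].items()}
    return v_match, v_mismatch


@dataclass
class Cohort:
    spec: PopulationSpec
    truth: pd.DataFrame  # subject, family, site, latent traits
    params: dict[str, LBAParams]

    @property
    def subjects(self) -> list[str]:
        return list(self.truth["subject"])


def generate_population(spec: PopulationSpec, seed=None) -> Cohort:
    """Draw per-subject true parameters, latent traits and nesting.

    Latents are multivariate normal; draws with non-positive threshold gap
    or out-of-range nondecision time are replaced by redraw.  Seeded and
    reproducible; an explicit ``seed`` overrides ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    k = len(LATENTS)
    sds = np.asarray(spec.latent_sds, dtype=float)
    cov = np.asarray(spec.latent_corr, dtype=float) * np.outer(sds, sds)
    means = np.asarray(spec.latent_means, dtype=float)

    draws = np.empty((spec.n_subjects, k))
    filled = 0
    for _ in range(1000):
        need = spec.n_subjects - filled
        if need == 0:
            break
        cand = rng.multivariate_normal(means, cov, size=need,
                                       method="cholesky")
        ok = (cand[:, 2] > 0.05) & (cand[:, 3] > 0.06) & (cand[:, 3] < 0.95)
        n_ok = int(ok.sum())
        draws[filled:filled + n_ok] = cand[ok]
        filled += n_ok
    if filled < spec.n_subjects:
        raise RuntimeError("latent redraw cap exceeded; check spec ranges")

    n_fam = spec.n_families or max(spec.n_subjects // 2, 1)
    family = np.array([f"fam{i % n_fam:03d}" for i in range(spec.n_subjects)])
    site = np.array([f"site{i % spec.n_sites}" for i in range(spec.n_subjects)])

    rows = []
    params: dict[str, LBAParams] = {}
    design = spec.design
    for i in range(spec.n_subjects):
        sid = f"s{i:03d}"
        eea, sea, B, t0, pgf_l = draws[i]
        p_gf = float(expit(pgf_l))
        v_match, v_mismatch = rates_from_traits(eea, sea, spec.task)
        params[sid] = LBAParams(
            v_match=v_match, v_mismatch=v_mismatch, A=spec.A,
            B={r: float(B) for r in design.responses},
            t0=float(t0), p_gf=p_gf, sv_mismatch=spec.sv_mismatch,
        )
        rows.append(
            {
                "subject": sid, "family": family[i], "site": site[i],
                "EEA_true": eea, "SEA_true": sea, "B_true": B,
                "t0_true": t0, "p_gf_true": p_gf,
            }
        )
    return Cohort(spec=spec, truth=pd.DataFrame(rows), params=params)


def generate_trials(cohort: Cohort, seed=None,
                    window: float | None = None) -> list[SubjectDataset]:
    """Simulate every subject's trials from their true LBA parameters.

    ``window`` overrides the task's response window (e.g. a generous
    window to study the race without censoring).
    """
    spec = cohort.spec
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    design = spec.design
    nesting_by_subject = cohort.truth.set_index("subject")[["family", "site"]]
    datasets = []
    for sid in cohort.subjects:
        sub_rng = np.random.default_rng(rng.integers(2**31 - 1))
        ds = lba_simulate(cohort.params[sid], design,
                          spec.trials_per_condition, seed=sub_rng,
                          subject_id=sid, window=window)
        ds.nesting = nesting_by_subject.loc[sid].to_dict()
        datasets.append(ds)
    return datasets


def generate_criteria(cohort: Cohort, seed=None) -> pd.DataFrame:
    """Criterion scores: loading on standardized latent EEA plus noise.

    ``criterion = loading * z(EEA_true) + family intercept + site intercept
    + Normal(0, noise_sd)``, standardizing EEA by its population mean/SD
    from the spec so the loading is an exact population effect size.
    """
    spec = cohort.spec
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    truth = cohort.truth
    eea_mean = spec.latent_means[0]
    eea_sd = spec.latent_sds[0] if spec.latent_sds[0] > 0 else 1.0
    z = (truth["EEA_true"].to_numpy() - eea_mean) / eea_sd
    out = truth[["subject", "family", "site"]].copy()
    fams = truth["family"].unique()
    sites = truth["site"].unique()
    fam_idx = truth["family"].map({f: i for i, f in enumerate(fams)}).to_numpy()
    site_idx = truth["site"].map({s: i for i, s in enumerate(sites)}).to_numpy()
    for crit in spec.criteria:
        u_fam = rng.normal(0.0, crit.family_sd, size=len(fams))
        u_site = rng.normal(0.0, crit.site_sd, size=len(sites))
        eps = rng.normal(0.0, crit.noise_sd, size=len(truth))
        out[crit.name] = (crit.loading * z + u_fam[fam_idx]
                          + u_site[site_idx] + eps)
    return out


def generate_study(spec: PopulationSpec, seed=None):
    """Cohort + trials + criteria in one seeded call."""
    base = np.random.default_rng(spec.seed if seed is None else seed)
    s1, s2, s3 = (int(x) for x in base.integers(2**31 - 1, size=3))
    cohort = generate_population(spec, seed=s1)
    trials = generate_trials(cohort, seed=s2)
    criteria = generate_criteria(cohort, seed=s3)
    return cohort, trials, criteria


#: sweep grids for the EEA/SEA dissociation: EEA over its full population
#: range (mean +- 2 SD), SEA over its central range (mean +- 1.25 SD)
EEA_SWEEP = (0.5, 1.0, 1.5, 2.0, 2.5)
SEA_SWEEP = (1.25, 1.5, 1.75, 2.0, 2.25)


def dissociation_sweep(sweep: str, n_trials: int = 150_000, seed=None,
                       eea_fixed: float = 1.5, sea_fixed: float = 1.75,
                       grid=None, spec: PopulationSpec | None = None
                       ) -> pd.DataFrame:
    """Simulate accuracy and mean RT while sweeping one latent trait.

    ``sweep="SEA"`` holds EEA at its population mean and varies SEA (the
    prediction: mean RT falls monotonically while accuracy barely moves);
    ``sweep="EEA"`` holds SEA fixed and varies EEA (accuracy rises
    monotonically).  Accuracy and mean RT are computed over responded
    trials, aggregated across conditions.  Go failure is disabled so the
    sweep isolates the race itself.
    """
    spec = spec or PopulationSpec()
    design = spec.design
    if grid is None:
        grid = SEA_SWEEP if sweep == "SEA" else EEA_SWEEP
    rng = np.random.default_rng(seed)
    per_cond = max(n_trials // len(design.conditions), 1)
    rows = []
    for val in grid:
        eea, sea = ((eea_fixed, val) if sweep == "SEA" else (val, sea_fixed))
        v_match, v_mismatch = rates_from_traits(eea, sea, spec.task)
        p = LBAParams(
            v_match=v_match, v_mismatch=v_mismatch, A=spec.A,
            B={r: spec.latent_means[2] for r in design.responses},
            t0=spec.latent_means[3], p_gf=0.0, sv_mismatch=spec.sv_mismatch,
        )
        ds = lba_simulate(p, design, per_cond,
                          seed=np.random.default_rng(rng.integers(2**31 - 1)))
        resp = ds.trials[ds.trials["response"] != "omitted"]
        rows.append(
            {
                "sweep": sweep, "value": val, "EEA": eea, "SEA": sea,
                "accuracy": float(resp["correct"].mean()),
                "mean_rt": float(resp["rt"].mean()),
                "omission_rate": ds.omission_rate,
            }
        )
    return pd.DataFrame(rows)


def ddm_params_for(cohort: Cohort, a: float = 1.4, z_rel: float = 0.5,
                   st0: float = 0.1) -> dict[str, DDMParams]:
    """Optional DDM generating parameters with drift tied to latent EEA.

    Maps each subject's per-condition rate difference onto a DDM drift so
    studies can also be generated from (or compared against) the diffusion
    model; caution and nondecision carry over from the LBA traits.
    """
    out = {}
    for sid, p in cohort.params.items():
        v = {c: (p.v_match[c] - p.v_mismatch[c]) for c in p.v_match}
        out[sid] = DDMParams(v=v, a=a, z_rel=z_rel,
                             Ter=max(p.t0, st0 / 2.0 + 1e-3), st0=st0,
                             p_gf=p.p_gf)
    return out
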