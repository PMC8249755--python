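"""Synthetic study generation with known ground truth.

Emulates the structure of a two-group, three-session, two-condition
evoked-response study of ketamine effects: treatment-resistant depression
(TRD) and healthy volunteer (HV) groups, baseline / placebo / ketamine
sessions, angry and happy face conditions, four source regions. Each
subject-session receives log-scaling parameters drawn around second-level
effects (mean, group, drug, group x drug) with between-subject and
between-session variability; evoked responses are then simulated from the
neural-mass model and observation noise is added to a target SNR. Linked
clinical (MADRS) and behavioral (dot-probe) tables are generated with a
configurable coupling between ketamine-induced parameter changes and
depression-score changes.

Default injected group-level effects use the magnitudes this pipeline is
designed to detect: group-by-drug effects on the early-visual GABA rate
(-0.1274) and on NMDA rates in early visual (+0.1994), fusiform (-0.1723)
and amygdala (+0.1502), plus a drug effect on the amygdala NMDA rate
(+0.5303).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels
from ._assemble import param_names
from .group_peb import COVARIATES, DesignMatrix, build_design
from .network_models import NetworkSpec, build_model
from .nmm_core import ERPDataset, ModelParameters, _fixed_point_kernel

__all__ = [
    "TaskConfig", "TaskDesign", "StudyConfig", "SyntheticStudy",
    "ClinicalConfig", "generate_task_design", "generate_group_dataset",
    "generate_clinical_behavior", "study_free_params",
    "DEFAULT_INJECTED_BETA",
]

#: group-level effects injected by default (log-scaling units)
DEFAULT_INJECTED_BETA = {
    "kappa_gaba:EV": {"group_x_drug": -0.1274},
    "kappa_nmda:EV": {"group_x_drug": +0.1994},
    "kappa_nmda:Fusi": {"group_x_drug": -0.1723},
    "kappa_nmda:Amy": {"group_x_drug": +0.1502, "drug": +0.5303},
}


def study_free_params(spec: NetworkSpec) -> list[str]:
    """Parameters varied by the generator and freed in study-scale fits.

    Receptor rate constants everywhere, the early-visual spiny-stellate
    self-gain, the AMPA drive of every forward connection, and the
    per-edge emotion modulators.
    """
    return ([f"kappa_{ch}:{r}" for ch in ("ampa", "gaba", "nmda")
             for r in spec.regions]
            + ["G:EV:self_ss"]
            + [f"A_ampa:{a}->{b}" for a, b in spec.forward_edges]
            + [f"B:{a}->{b}" for a, b in spec.edges])


# ---------------------------------------------------------------------------
# dot-probe task design


@dataclass(frozen=True)
class TaskConfig:
    n_per_emotional_type: int = 48
    n_neutral_pairs: int = 96
    fixation_ms: float = 500.0
    faces_ms: float = 500.0
    probe_ms: float = 200.0
    isi_ms: float = 1300.0
    jitter_max_ms: float = 300.0


@dataclass
class TaskDesign:
    trials: pd.DataFrame
    config: TaskConfig

    def counts(self) -> pd.Series:
        return self.trials["trial_type"].value_counts()


def generate_task_design(config: TaskConfig | None = None,
                         seed=0) -> TaskDesign:
    """Block-randomized dot-probe trial list.

    Two angry and two happy blocks; emotional trials are split evenly over
    the two blocks of their emotion and counterbalanced for the side of
    the emotional face (probe side then follows congruency); neutral pairs
    are spread over all four blocks with balanced probe side.
    """
    cfg = config or TaskConfig()
    if cfg.n_per_emotional_type % 4 or cfg.n_neutral_pairs % 4:
        raise ValueError("trial counts must be divisible by 4 for "
                         "side/congruency counterbalancing")
    rng = np.random.default_rng(seed)
    blocks = ["angry_1", "angry_2", "happy_1", "happy_2"]
    rng.shuffle(blocks)
    rows = []
    per_type_block = cfg.n_per_emotional_type // 2  # each type spans 2 blocks
    for block in blocks:
        emotion = block.split("_")[0]
        for congruent in (True, False):
            for i in range(per_type_block):
                emo_side = "left" if i < per_type_block // 2 else "right"
                probe_side = (emo_side if congruent else
                              ("right" if emo_side == "left" else "left"))
                rows.append({
                    "block": block,
                    "trial_type": f"{emotion}_{'cong' if congruent else 'incong'}",
                    "emotional_side": emo_side,
                    "probe_side": probe_side,
                })
        for i in range(cfg.n_neutral_pairs // 4):
            rows.append({
                "block": block,
                "trial_type": "neutral_pair",
                "emotional_side": "none",
                "probe_side": "left" if i % 2 == 0 else "right",
            })
    df = pd.DataFrame(rows)
    # randomize trial order within blocks, keep the block order
    parts = []
    for block in blocks:
        g = df[df.block == block].reset_index(drop=True)
        parts.append(g.iloc[rng.permutation(len(g))])
    df = pd.concat(parts, ignore_index=True)
    df["jitter_ms"] = rng.uniform(0, cfg.jitter_max_ms, len(df)).round(1)
    return TaskDesign(trials=df, config=cfg)


# ---------------------------------------------------------------------------
# group ERP study


@dataclass(frozen=True)
class StudyConfig:
    n_trd: int = 19
    n_hv: int = 15
    sessions: tuple = ("baseline", "placebo", "ketamine")
    conditions: tuple = ("angry", "happy")
    model_id: int = 2
    snr: float = 4.0              # signal RMS / noise SD over 1-500 ms
    epoch_ms: tuple = (-100.0, 500.0)
    dt_ms: float = 2.0
    between_subject_sd: float = 0.02
    between_session_sd: float = 0.02
    injected_beta: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_INJECTED_BETA.items()})
    simulate_erps: bool = True


@dataclass
class SyntheticStudy:
    config: StudyConfig
    seed: int
    roster: pd.DataFrame                 # subject_id, group
    design: DesignMatrix                 # subject-session rows
    varied_params: tuple
    beta_true: pd.DataFrame              # param x covariate
    truth: pd.DataFrame                  # row per subject-session, col per param
    erp: ERPDataset | None
    noise_sd: float
    spec: NetworkSpec

    def truth_change(self, param: str, sess_a: str = "baseline",
                     sess_b: str = "ketamine",
                     group: str = "TRD") -> pd.Series:
        """Per-subject true parameter change sess_a minus sess_b."""
        t = self.truth.copy()
        t["subject_id"] = [r[0] for r in self.design.rows]
        t["session"] = [r[1] for r in self.design.rows]
        keep = self.roster.set_index("subject_id")["group"]
        t = t[t["subject_id"].map(keep) == group]
        a = t[t.session == sess_a].set_index("subject_id")[param]
        b = t[t.session == sess_b].set_index("subject_id")[param]
        return a - b


def _simulate_cells(params0: ModelParameters, spec: NetworkSpec,
                    values_list, conditions, t_grid) -> np.ndarray:
    """Batched noiseless simulation: (n_cells*n_cond, n_regions, n_t)."""
    t = np.asarray(t_grid, dtype=float)
    dt = float(t[1] - t[0])
    cm = params0.constants["Cm"]
    out = []
    V = np.asarray(values_list, dtype=float)
    for cond in conditions:
        tpl = params0.template(spec, cond)
        arr = tpl.materialize(V)
        Xeq, _ = _fixed_point_kernel(tpl, arr, 1e-8 * cm * 0.5)
        k = tpl.consts
        y, _, _ = _kernels.rk4_run(
            Xeq, tpl.rowsA, tpl.colsA, arr["wA"], tpl.rowsG, tpl.colsG,
            arr["wG"], tpl.rowsN, tpl.colsN, arr["wN"],
            arr["kapA"], arr["kapG"], arr["kapN"], tpl.cmask,
            arr["onset"], arr["width"], arr["amp"],
            t[0], dt, t.size - 1,
            k[0], k[1], k[2], k[3], k[4], k[5], k[6], k[7],
            tpl.jw, arr["obsg"], Xeq[:, :16].copy(), False)
        out.append(y)
    return out


def generate_group_dataset(config: StudyConfig | None = None,
                           seed=0) -> SyntheticStudy:
    """Full synthetic study: roster, true parameters and (optionally) ERPs.

    Subject-session log-scalings are lambda = X beta_true + b_subject +
    e_session with seeded Gaussian variability; evoked responses are
    simulated from the generating architecture and observation noise is
    scaled so that (default-signal RMS / noise SD) over the positive-time
    window equals the configured SNR.
    """
    cfg = config or StudyConfig()
    rng = np.random.default_rng(seed)
    spec = build_model(cfg.model_id)
    varied = study_free_params(spec)
    all_names = param_names(spec)
    unknown = [p for p in cfg.injected_beta if p not in all_names]
    if unknown:
        raise ValueError(f"injected effects on unknown parameters: {unknown}")
    roster = pd.DataFrame({
        "subject_id": [f"trd{i + 1:02d}" for i in range(cfg.n_trd)]
        + [f"hv{i + 1:02d}" for i in range(cfg.n_hv)],
        "group": ["TRD"] * cfg.n_trd + ["HV"] * cfg.n_hv,
    })
    design = build_design(list(zip(roster.subject_id, roster.group)),
                          cfg.sessions)
    P = len(varied)
    beta = pd.DataFrame(0.0, index=varied, columns=list(COVARIATES))
    for pname, effs in cfg.injected_beta.items():
        for cov, val in effs.items():
            if pname in beta.index:
                beta.loc[pname, cov] = val
    n_rows = design.X.shape[0]
    lam = design.X @ beta.to_numpy().T  # (n_rows, P)
    b_subj = rng.normal(0.0, cfg.between_subject_sd,
                        size=(len(roster), P))
    n_sessions = len(cfg.sessions)
    lam = lam + np.repeat(b_subj, n_sessions, axis=0)
    lam = lam + rng.normal(0.0, cfg.between_session_sd, size=(n_rows, P))
    truth = pd.DataFrame(lam, columns=varied)

    erp = None
    noise_sd = np.nan
    if cfg.simulate_erps:
        t_grid = np.arange(cfg.epoch_ms[0], cfg.epoch_ms[1] + cfg.dt_ms / 2,
                           cfg.dt_ms)
        params0 = ModelParameters.default(spec)
        base = params0.template(spec, cfg.conditions[0]).values_matrix(params0)[0]
        idx = [all_names.index(n) for n in varied]
        values = np.tile(base, (n_rows, 1))
        values[:, idx] = base[idx][None, :] + lam
        sims = _simulate_cells(params0, spec, values, cfg.conditions, t_grid)
        ref = _simulate_cells(params0, spec, base[None, :], cfg.conditions,
                              t_grid)
        mask = t_grid >= 1.0
        # per-region noise: source time series are scaled region-wise, so
        # the SNR target applies to every region's own signal RMS
        reg_rms = np.sqrt(np.mean(np.stack(ref)[:, 0, :, :][:, :, mask] ** 2,
                                  axis=(0, 2)))
        noise_sd_r = reg_rms / cfg.snr
        noise_sd = float(np.sqrt(np.mean(noise_sd_r ** 2)))
        cells = []
        amps = []
        for ci, cond in enumerate(cfg.conditions):
            for i, (sid, ses) in enumerate(design.rows):
                grp = roster.set_index("subject_id")["group"][sid]
                cells.append({"subject_id": sid, "group": grp,
                              "session": ses, "condition": cond})
                amps.append(sims[ci][i])
        amps = np.stack(amps)
        amps = amps + rng.normal(0.0, 1.0, size=amps.shape) \
            * noise_sd_r[None, :, None]
        erp = ERPDataset(amps, pd.DataFrame(cells), tuple(spec.regions),
                         t_grid, meta={"seed": int(seed), "noise_sd": noise_sd,
                                       "snr": cfg.snr,
                                       "model_id": cfg.model_id})
    return SyntheticStudy(config=cfg, seed=int(seed), roster=roster,
                          design=design, varied_params=tuple(varied),
                          beta_true=beta, truth=truth, erp=erp,
                          noise_sd=noise_sd, spec=spec)


# ---------------------------------------------------------------------------
# clinical / behavioral tables


@dataclass(frozen=True)
class ClinicalConfig:
    #: (mean, sd) of MADRS per session x timepoint for the TRD group
    ketamine_pre: tuple = (33.37, 4.39)
    ketamine_post_sd: float = 11.06
    placebo_pre: tuple = (32.26, 4.79)
    placebo_post: tuple = (31.21, 5.03)
    ketamine_change_mean: float = 6.42  # 33.37 - 26.95
    #: couplings between true baseline-minus-ketamine parameter change and
    #: the ketamine MADRS improvement: (parameter, target correlation)
    couplings: tuple = (("kappa_ampa:EV", 0.4917), ("G:EV:self_ss", -0.6545))
    coupling_noise: float | None = None  # None -> calibrated to targets
    accuracy_group_mean: dict = field(default_factory=lambda: {
        "TRD": 94.2, "HV": 88.8})
    accuracy_session_offset: dict = field(default_factory=lambda: {
        "baseline": +2.3, "ketamine": -0.3, "placebo": -2.1})
    accuracy_subject_sd: float = 2.0
    rt_mean_ms: float = 520.0
    rt_sd_ms: float = 60.0
    rt_congruency_bias_ms: float = 0.0
    n_trials_per_cell: int = 48


def generate_clinical_behavior(study: SyntheticStudy,
                               config: ClinicalConfig | None = None,
                               seed=0):
    """Linked MADRS and dot-probe behavior tables for a synthetic study.

    The TRD ketamine-session MADRS improvement is a linear combination of
    the standardized true baseline-minus-ketamine changes of the coupled
    parameters plus Gaussian noise, with weights solved so the population
    correlations match the configured targets (|r| must be < 1). Healthy
    volunteers receive behavior rows only.
    """
    cfg = config or ClinicalConfig()
    rng = np.random.default_rng(seed)
    trd = study.roster[study.roster.group == "TRD"]
    if trd.empty:
        raise ValueError("study contains no TRD subjects")
    for _, r in cfg.couplings:
        if abs(r) >= 1:
            raise ValueError(f"coupling correlation must satisfy |r| < 1, got {r}")
    n = len(trd)
    # standardized true parameter changes (baseline - ketamine)
    Z = np.empty((n, len(cfg.couplings)))
    for j, (pname, _) in enumerate(cfg.couplings):
        if pname not in study.truth.columns:
            raise ValueError(f"coupled parameter {pname!r} not varied by the "
                             "generator")
        ch = study.truth_change(pname).loc[trd.subject_id].to_numpy()
        sd = ch.std(ddof=0)
        Z[:, j] = (ch - ch.mean()) / (sd if sd > 0 else 1.0)
    targets = np.array([r for _, r in cfg.couplings])
    G = (Z.T @ Z) / n
    w = np.linalg.solve(G, targets)
    if cfg.coupling_noise is None:
        s2 = max(0.0, 1.0 - float(w @ targets))
        s = np.sqrt(s2)
    else:
        s = float(cfg.coupling_noise)
    raw = Z @ w + s * rng.normal(size=n)
    sd = raw.std(ddof=0)
    madrs_z = raw / (sd if sd > 0 else 1.0)

    k_pre = rng.normal(*cfg.ketamine_pre, size=n)
    p_pre = rng.normal(*cfg.placebo_pre, size=n)
    p_post = rng.normal(*cfg.placebo_post, size=n)
    change_sd = np.sqrt(max(cfg.ketamine_post_sd ** 2
                            - cfg.ketamine_pre[1] ** 2, 1.0))
    k_change = cfg.ketamine_change_mean + change_sd * madrs_z
    k_post = k_pre - k_change
    rows = []
    for i, sid in enumerate(trd.subject_id):
        for ses, pre, post in (("ketamine", k_pre[i], k_post[i]),
                               ("placebo", p_pre[i], p_post[i])):
            rows.append({"subject_id": sid, "group": "TRD", "session": ses,
                         "timepoint_min": -60, "madrs": np.clip(pre, 0, 60)})
            rows.append({"subject_id": sid, "group": "TRD", "session": ses,
                         "timepoint_min": 230, "madrs": np.clip(post, 0, 60)})
    clinical = pd.DataFrame(rows)

    brows = []
    for _, subj in study.roster.iterrows():
        acc_subj = rng.normal(0.0, cfg.accuracy_subject_sd)
        for ses in study.config.sessions:
            p_correct = np.clip(
                (cfg.accuracy_group_mean[subj.group]
                 + cfg.accuracy_session_offset[ses] + acc_subj) / 100.0,
                0.05, 1.0)
            for emotion in ("angry", "happy"):
                for cong in ("congruent", "incongruent"):
                    nt = cfg.n_trials_per_cell
                    correct = rng.random(nt) < p_correct
                    bias = (-cfg.rt_congruency_bias_ms / 2
                            if cong == "congruent"
                            else +cfg.rt_congruency_bias_ms / 2)
                    rt = rng.normal(cfg.rt_mean_ms + bias, cfg.rt_sd_ms, nt)
                    for k in range(nt):
                        brows.append({
                            "subject_id": subj.subject_id,
                            "group": subj.group, "session": ses,
                            "emotion": emotion, "congruency": cong,
                            "correct": bool(correct[k]),
                            "rt_ms": max(150.0, rt[k]),
                        })
    behavior = pd.DataFrame(brows)
    return clinical, behavior
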