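"""End-to-end synthetic-cohort analysis: simulate -> preprocess -> behavior ->
spectral -> cluster statistics -> source.

The cohort mirrors the clinical design: patients recorded in two sessions
(stimulator OFF and ON; paired contrasts) and an independent control group
(independent contrasts).  Group-level ground truth defaults state a world in
which the OFF state has a shallower psychometric curve, weaker beta
suppression and weaker delta phase locking than controls, while the ON state
restores behavior and beta suppression but not delta ITPC — the qualitative
pattern the analysis should recover.

``run_pipeline`` is deterministic given the root seed: every stage draws
from a named substream.  All sizes (trials, channels, sampling rate, wavelet
count, grid spacing, permutations) are configurable so the same code runs as
a quick smoke cohort or at full session scale.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._rng import substream
from . import behavior as bhv
from . import cluster as cst
from . import source as src
from .layout import SensorLayout, standard_layout
from .preprocess import FilterSpec, epoch, filter_continuous, no_op_ica
from .simulate import ObserverParams, OscillatoryTruth, simulate_eeg, \
    simulate_responses
from .spectral import EventWindows, align, band_window_average, \
    baseline_normalize, build_bank, convolve, itpc, power_binned
from .task import TaskDesign, build_schedule

__all__ = ["GroupTruth", "PipelineConfig", "SubjectResult", "CohortResult",
           "run_pipeline", "analyze_session"]


@dataclass(frozen=True)
class GroupTruth:
    """Population-level generator parameters for one group/condition."""

    steepness: float
    pse_ms: float = 0.0
    beta_suppression: float = -0.4
    delta_kappa: float = 2.0
    steepness_cv: float = 0.25   # between-subject lognormal spread
    pse_sd_ms: float = 30.0
    kappa_cv: float = 0.25


# defaults: the qualitative clinical pattern (OFF impaired, ON restored
# behavior/beta but not delta ITPC) at plausible effect sizes
DEFAULT_GROUPS = {
    "off": GroupTruth(steepness=0.0015, beta_suppression=-0.10, delta_kappa=0.8),
    "on": GroupTruth(steepness=0.0030, beta_suppression=-0.35, delta_kappa=0.9),
    "control": GroupTruth(steepness=0.0040, beta_suppression=-0.40,
                          delta_kappa=2.0),
}


@dataclass
class PipelineConfig:
    n_patients: int = 13
    n_controls: int = 20
    n_trials: int | None = None          # default: full 480-trial session
    design: TaskDesign = field(default_factory=TaskDesign)
    groups: dict = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    n_channels: int = 64
    wavelet_n: int = 40
    wavelet_fmin: float = 0.5
    wavelet_fmax: float = 100.0
    windows: EventWindows = field(default_factory=EventWindows)
    beta_band: tuple = (13.0, 30.0)
    beta_window_ms: tuple = (-200.0, 600.0)   # around disappearance
    delta_band: tuple = (0.5, 4.0)
    delta_window_ms: tuple = (-200.0, 900.0)  # around disappearance
    n_perm: int = 1000
    cluster_alpha: float = 0.05
    source_spacing_mm: float | None = None    # None: skip source stage
    lambda_frac: float = 0.05
    couple_itpc_behavior: bool = False        # subject kappa tracks steepness
    snr: float = 1.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        """Load a config from YAML; nested design/groups blocks supported."""
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "design" in raw:
            raw["design"] = TaskDesign(**{
                k: tuple(v) if k == "delta_levels" else v
                for k, v in raw["design"].items()})
        if "groups" in raw:
            # YAML 1.1 parses bare `on`/`off` keys as booleans
            names = {True: "on", False: "off"}
            raw["groups"] = {names.get(k, k): GroupTruth(**v)
                             for k, v in raw["groups"].items()}
        for key in ("beta_band", "beta_window_ms", "delta_band",
                    "delta_window_ms"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.wavelet_fmax > self.design.sampling_rate / 2:
            raise ValueError("wavelet_fmax above Nyquist")
        for g in ("off", "on", "control"):
            if g not in self.groups:
                raise ValueError(f"missing group truth: {g}")


@dataclass
class SubjectResult:
    subject: str
    session: str
    fit: bhv.PsychometricFit
    n_scheduled: int
    n_epochs: int
    n_correct: int
    power_maps: dict            # window -> BinnedMap (relative power)
    itpc_maps: dict             # window -> BinnedMap
    beta_channel_avg: np.ndarray
    delta_itpc_channel_avg: np.ndarray
    truth: dict


def _draw_observer(g: GroupTruth, rng: np.random.Generator) -> ObserverParams:
    s = g.steepness * np.exp(rng.normal(0, g.steepness_cv))
    pse = rng.normal(g.pse_ms, g.pse_sd_ms)
    return ObserverParams(pse_ms=pse, steepness=s)


def analyze_session(recording, schedule, table, cfg: PipelineConfig,
                    subject: str, session: str, layout: SensorLayout,
                    bank) -> SubjectResult:
    """Filter -> epoch -> psychometrics -> subjectively-correct TFR maps."""
    filtered = filter_continuous(recording, FilterSpec())
    eps = no_op_ica(epoch(filtered, schedule, cfg.design))
    fit = bhv.fit_psychometric(bhv.proportions(table))
    correct = bhv.subjectively_correct(table, fit)
    correct_ids = set(table.loc[correct, "trial_id"])
    eps_ok = [e for e in eps if e.trial_id in correct_ids]

    tfrs, valids = [], []
    for e in eps_ok:
        c, v = convolve(e.data, bank)
        tfrs.append(c)
        valids.append(v)

    fs = cfg.design.sampling_rate
    power_maps, itpc_maps = {}, {}
    aligned_by_window = {}
    for name, win in cfg.windows.items():
        ev_name = {"baseline": "move_on", "movement": "move_on",
                   "disappearance": "disappear", "reappearance": "reappear"}[name]
        evs = [e.events[ev_name] for e in eps_ok]
        tfr = align(tfrs, valids, evs, win, fs, bank.freqs)
        aligned_by_window[name] = tfr
        power_maps[name] = power_binned(tfr)
        itpc_maps[name] = itpc(tfr)

    # pre-movement normalization baseline (-500 to -200 ms re movement onset)
    evs = [e.events["move_on"] for e in eps_ok]
    base_tfr = align(tfrs, valids, evs, cfg.windows.norm_baseline, fs, bank.freqs)
    base_map = power_binned(base_tfr)
    for name in list(power_maps):
        power_maps[name] = baseline_normalize(power_maps[name], base_map,
                                              mode="relative")

    beta_avg = band_window_average(power_maps["disappearance"], cfg.beta_band,
                                   cfg.beta_window_ms, require_valid=False)
    delta_avg = band_window_average(itpc_maps["disappearance"], cfg.delta_band,
                                    cfg.delta_window_ms, require_valid=False)
    truth = recording.meta.get("truth") if recording.meta else None
    return SubjectResult(
        subject, session, fit, len(schedule), len(eps), int(correct.sum()),
        power_maps, itpc_maps, beta_avg, delta_avg,
        {"observer": None, "oscillatory": truth},
    ), aligned_by_window


@dataclass
class CohortResult:
    subjects: list
    behavioral: dict      # contrast name -> GroupTest
    sensor_clusters: dict  # contrast name -> ClusterResult
    source_clusters: dict
    summary: dict
    config_hash: str

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary, fh, indent=2, sort_keys=True)


def _config_hash(cfg: PipelineConfig) -> str:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dict__") or hasattr(o, "__dataclass_fields__"):
            return asdict(o) if hasattr(o, "__dataclass_fields__") else vars(o)
        return str(o)
    blob = json.dumps(asdict(cfg), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _simulate_subject(cfg: PipelineConfig, layout, group: str, idx: int,
                      session_key: str):
    g: GroupTruth = cfg.groups[group]
    rng = substream(cfg.seed, "cohort", group, idx)
    observer = _draw_observer(g, rng)
    kappa = g.delta_kappa * np.exp(rng.normal(0, g.kappa_cv))
    if cfg.couple_itpc_behavior:
        # phase-locking strength tracks behavioral precision across subjects
        kappa = g.delta_kappa * observer.steepness / g.steepness
    truth = OscillatoryTruth(beta_suppression=g.beta_suppression,
                             delta_kappa=float(kappa), snr=cfg.snr)
    sub_seed = int(substream(cfg.seed, "seeds", group, idx,
                             session_key).integers(2**31))
    schedule = build_schedule(cfg.design, cfg.n_trials, seed=sub_seed)
    table = simulate_responses(schedule, observer, seed=sub_seed)
    rec = simulate_eeg(schedule, truth, layout, cfg.design, seed=sub_seed)
    return rec, schedule, table, observer, truth


def run_pipeline(cfg: PipelineConfig, out_dir: str | None = None,
                 make_figures: bool = False) -> CohortResult:
    """Simulate and analyze a full cohort; returns all contrast objects.

    Stages: simulate -> filter -> epoch -> psychometric fit and
    subjectively-correct selection -> wavelet power/ITPC maps -> sensor
    cluster statistics (vs baseline, OFF-ON paired, OFF/ON vs control
    independent) -> optional DICS source stage (beta power contrasts, delta
    ITPC, ITPC-steepness correlation).
    """
    cfg.validate()
    layout = standard_layout(cfg.n_channels)
    bank = build_bank(cfg.wavelet_fmin, cfg.wavelet_fmax, cfg.wavelet_n,
                      fs=cfg.design.sampling_rate)
    sessions = ([("patient", i, s) for i in range(cfg.n_patients)
                 for s in ("off", "on")]
                + [("control", i, "control") for i in range(cfg.n_controls)])

    results: dict[tuple[str, str], SubjectResult] = {}
    aligned_store: dict[tuple[str, str], dict] = {}
    for kind, idx, sess in sessions:
        name = f"{kind}{idx:02d}"
        rec, schedule, table, observer, truth = _simulate_subject(
            cfg, layout, sess, idx, sess)
        sr, aligned = analyze_session(rec, schedule, table, cfg, name, sess,
                                      layout, bank)
        sr.truth["observer"] = observer
        results[(name, sess)] = sr
        aligned_store[(name, sess)] = aligned

    def stack(sess: str, attr: str) -> np.ndarray:
        return np.stack([getattr(r, attr) for (nm, s), r in results.items()
                         if s == sess])

    # ---------------- behavioral group statistics
    steep = {s: np.array([r.fit.steepness for (nm, ss), r in results.items()
                          if ss == s]) for s in ("off", "on", "control")}
    pse = {s: np.array([r.fit.pse_ms for (nm, ss), r in results.items()
                        if ss == s]) for s in ("off", "on", "control")}
    behavioral = {
        "steepness_off_vs_on": bhv.group_stats(steep["off"], steep["on"],
                                               design="paired"),
        "steepness_off_vs_control": bhv.group_stats(steep["off"],
                                                    steep["control"],
                                                    design="independent"),
        "steepness_on_vs_control": bhv.group_stats(steep["on"],
                                                   steep["control"],
                                                   design="independent"),
        "pse_off_vs_zero": bhv.group_stats(pse["off"],
                                           design="one-sample-vs-zero"),
        "pse_on_vs_zero": bhv.group_stats(pse["on"],
                                          design="one-sample-vs-zero"),
        "pse_control_vs_zero": bhv.group_stats(pse["control"],
                                               design="one-sample-vs-zero"),
    }

    # ---------------- sensor-level cluster statistics
    adj_ch = cst.combined_adjacency(layout.adjacency, 1, 1)
    sensor_clusters = {}
    for contrast, (sa, sb, kind) in {
        "beta_off_vs_on": ("off", "on", "paired_t"),
        "beta_off_vs_control": ("off", "control", "independent_t"),
        "beta_on_vs_control": ("on", "control", "independent_t"),
    }.items():
        A = stack(sa, "beta_channel_avg")[:, :, None, None]
        B = stack(sb, "beta_channel_avg")[:, :, None, None]
        sensor_clusters[contrast] = cst.permutation_p(
            A, B, kind=kind, adj=adj_ch, n_perm=cfg.n_perm,
            cluster_alpha=cfg.cluster_alpha, seed=cfg.seed)
    for contrast, (sa, sb, kind) in {
        "delta_itpc_off_vs_control": ("off", "control", "independent_t"),
        "delta_itpc_on_vs_control": ("on", "control", "independent_t"),
        "delta_itpc_off_vs_on": ("off", "on", "paired_t"),
    }.items():
        A = stack(sa, "delta_itpc_channel_avg")[:, :, None, None]
        B = stack(sb, "delta_itpc_channel_avg")[:, :, None, None]
        sensor_clusters[contrast] = cst.permutation_p(
            A, B, kind=kind, adj=adj_ch, n_perm=cfg.n_perm,
            cluster_alpha=cfg.cluster_alpha, seed=cfg.seed)
    # beta vs baseline within each session type (one-sample on relative power)
    for sess in ("off", "on", "control"):
        A = stack(sess, "beta_channel_avg")[:, :, None, None]
        sensor_clusters[f"beta_vs_baseline_{sess}"] = cst.permutation_p(
            A, kind="one_sample_t", adj=adj_ch, n_perm=cfg.n_perm,
            cluster_alpha=cfg.cluster_alpha, seed=cfg.seed)

    # ---------------- source stage (optional)
    source_clusters = {}
    if cfg.source_spacing_mm is not None:
        head = src.HeadModel()
        grid = src.build_grid(head, spacing_mm=cfg.source_spacing_mm)
        lf = src.leadfield_sphere(grid, layout, head)
        adj_vox = cst.combined_adjacency(src.grid_adjacency(grid), 1, 1)
        delta_bank_sel = (bank.freqs >= cfg.delta_band[0]) & \
                         (bank.freqs <= cfg.delta_band[1])
        itpc_by_sess: dict[str, list[np.ndarray]] = {"off": [], "on": [],
                                                     "control": []}
        steep_by_sess: dict[str, list[float]] = {"off": [], "on": [],
                                                 "control": []}
        for (nm, sess), sr in results.items():
            tfr = aligned_store[(nm, sess)]["disappearance"]
            C, centers = src.csd(tfr.coefficients, tfr.times_ms)
            Cavg = src.csd_band_average(C, bank.freqs, centers,
                                        cfg.delta_band, cfg.delta_window_ms)
            filt = src.dics_filters(Cavg, lf, cfg.lambda_frac)
            vi = src.source_itpc(filt, tfr.coefficients, tfr.times_ms,
                                 bank.freqs, cfg.delta_band,
                                 cfg.delta_window_ms)
            itpc_by_sess[sess].append(vi)
            steep_by_sess[sess].append(sr.fit.steepness)
        for contrast, (sa, sb, kind) in {
            "src_delta_itpc_off_vs_control": ("off", "control", "independent_t"),
            "src_delta_itpc_on_vs_control": ("on", "control", "independent_t"),
        }.items():
            A = np.stack(itpc_by_sess[sa])[:, :, None, None]
            B = np.stack(itpc_by_sess[sb])[:, :, None, None]
            source_clusters[contrast] = cst.permutation_p(
                A, B, kind=kind, adj=adj_vox, n_perm=cfg.n_perm,
                cluster_alpha=cfg.cluster_alpha, seed=cfg.seed)
        if cfg.n_patients >= 4:  # Pearson r needs at least 4 subjects
            X = np.stack(itpc_by_sess["on"])[:, :, None, None]
            source_clusters["src_itpc_steepness_corr_on"] = cst.permutation_p(
                X, scores=np.array(steep_by_sess["on"]), kind="pearson_r",
                adj=adj_vox, n_perm=cfg.n_perm,
                cluster_alpha=cfg.cluster_alpha, seed=cfg.seed)

    summary = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "n_subjects": {"patients": cfg.n_patients, "controls": cfg.n_controls},
        "behavior": {k: {"t": v.t, "df": v.df, "p": v.p, "d": v.cohens_d,
                         "flagged": v.flagged}
                     for k, v in behavioral.items()},
        "sensor_clusters": {k: {"n_clusters": len(v.clusters),
                                "min_p": v.min_p,
                                "max_mass_sign": int(max(
                                    v.clusters, key=lambda c: abs(c.mass)).sign)
                                if v.clusters else 0}
                            for k, v in sensor_clusters.items()},
        "source_clusters": {k: {"n_clusters": len(v.clusters),
                                "min_p": v.min_p}
                            for k, v in source_clusters.items()},
        "trial_accounting": {f"{nm}:{sess}": {
            "scheduled": r.n_scheduled, "epochs": r.n_epochs,
            "subjectively_correct": r.n_correct}
            for (nm, sess), r in results.items()},
        "steepness_truth_vs_fit": {
            sess: {"mean_fit": float(np.mean(steep[sess]))}
            for sess in ("off", "on", "control")},
    }
    out = CohortResult(list(results.values()), behavioral, sensor_clusters,
                       source_clusters, summary, summary["config_hash"])
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        out.to_json(os.path.join(out_dir, "summary.json"))
        tables = []
        for (nm, sess), r in results.items():
            tables.append({"subject": nm, "session": sess,
                           "pse_ms": r.fit.pse_ms,
                           "steepness": r.fit.steepness,
                           "n_correct": r.n_correct})
        pd.DataFrame(tables).to_csv(os.path.join(out_dir, "behavior.tsv"),
                                    sep="\t", index=False)
        if make_figures:
            _figures(results, out_dir)
    return out


def _figures(results, out_dir: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    (nm, sess), sr = next(iter(results.items()))
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    mp = sr.power_maps["disappearance"]
    axes[0].imshow(mp.values.mean(axis=0), aspect="auto", origin="lower",
                   extent=[mp.bin_centers_ms[0], mp.bin_centers_ms[-1], 0,
                           len(mp.freqs)])
    axes[0].set_title(f"relative power, disappearance ({nm} {sess})")
    im = sr.itpc_maps["disappearance"]
    axes[1].imshow(im.values.mean(axis=0), aspect="auto", origin="lower",
                   extent=[im.bin_centers_ms[0], im.bin_centers_ms[-1], 0,
                           len(im.freqs)])
    axes[1].set_title("ITPC, disappearance")
    fig.tight_layout()
    fig.savefig(os.path.join(out_dir, "tfr_example.png"), dpi=100)
    plt.close(fig)
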