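"""Synthetic cohort generator: task-structured EEG with configurable
frontal-alpha asymmetry effects, plus coupled questionnaire scores.

The generator emulates a three-group mild-TBI study: a Go/NoGo task of 16
blocks × 64 trials with emotion (threat/neutral) and relevance
(relevant/irrelevant) manipulations, continuous 500 Hz EEG on a minimal
montage {F3, F4, Fz, Cz, VEOG}, 10 Hz alpha whose F4/F3 power ratio is set
per trial condition, 1/f pink background noise, and Poisson blink
artifacts on the EOG that propagate to frontal channels.

Power calibration: a sinusoid of amplitude A carries A²/2 mean-square
power, and the analysis pipeline's Hann periodogram band AUC recovers that
power; the generator inverts this exactly (including the per-trial edge
taper's mean square).  When pink noise is on, its known alpha-band AUC ν
adds to both electrodes and would shrink measured ln-ratios toward zero,
so cell powers are solved from (P4+ν)/(P3+ν) = e^target — the pipeline
then recovers the target FAA in expectation with noise on as well.

Questionnaires are coupled to each subject's latent eFAA through a
Gaussian copula with skewed count marginals; the latent Pearson
correlation is set to 2·sin(π·ρ_s/6) so the *Spearman* correlation hits
the configured target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from efaa import reference
from efaa.io_formats import Marker, Recording
from efaa.preprocess import encode_condition

FS_HZ = 500.0
MONTAGE = ("F3", "F4", "Fz", "Cz", "VEOG")
EPOCH_S = 2.0
BASELINE_S = 0.2

#: minimum pink-noise frequency (Hz); the 1/f shaping is flat below this
PINK_FLOOR_HZ = 0.5


def _default_group_faa() -> dict:
    return {
        g: {(emo, rel): reference.GROUP_FAA[g][emo]
            for emo in ("threat", "neutral")
            for rel in ("relevant", "irrelevant")}
        for g in reference.GROUP_SIZES
    }


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults reproduce the modelled study: group sizes 17/12/15, the
    published group × emotion FAA means, eFAA↔questionnaire Spearman
    couplings (BDI −0.52, RPQ −0.34, PTA +0.41) and the 16 × 64 task.
    """

    n_control: int = reference.GROUP_SIZES["Control"]
    n_nonsymp: int = reference.GROUP_SIZES["NonSymp"]
    n_symp: int = reference.GROUP_SIZES["Symp"]
    group_faa: dict = field(default_factory=_default_group_faa)
    base_power_f3: float = 5.0          # µV², alpha AUC at F3
    alpha_freq_hz: float = 10.0
    noise_rms_uv: float = 5.0           # pink-noise RMS per channel
    blink_rate_per_min: float = 12.0
    blink_amplitude_uv: float = 400.0   # VEOG peak
    blink_propagation: float = 0.3      # frontal-channel fraction
    faa_subject_sd: float = reference.FAA_SUBJECT_SD
    efaa_subject_sd: float = reference.EFAA_SUBJECT_SD
    cell_jitter_sd: float = 0.02        # idiosyncratic per-cell FAA jitter
    coupling: dict = field(default_factory=lambda: dict(reference.COUPLING))
    n_blocks: int = 16
    trials_per_block: int = 64
    iti_range_s: tuple[float, float] = (2.5, 3.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_control, self.n_nonsymp, self.n_symp) < 1:
            raise ValueError("group sizes must be >= 1")
        if self.base_power_f3 <= 0:
            raise ValueError("base alpha power must be positive")
        if self.blink_amplitude_uv <= 80:
            raise ValueError(
                "blink amplitude must exceed the 80 µV rejection limit")
        for k, rho in self.coupling.items():
            if abs(rho) >= 1:
                raise ValueError(f"|coupling rho| must be < 1 ({k}={rho})")
        if self.n_blocks % 4 or self.trials_per_block % 4:
            raise ValueError("blocks must divide by 4 (rules) and trials "
                             "per block by 4 (emotion × response balance)")

    @property
    def group_sizes(self) -> dict[str, int]:
        return {"Control": self.n_control, "NonSymp": self.n_nonsymp,
                "Symp": self.n_symp}


@dataclass
class Trial:
    block: int          # 1-based
    trial: int          # 1-based within block
    rule_id: int        # 1..4; rules 1-2 attend colour, 3-4 attend figure
    emotion: str
    relevance: str
    response: str
    onset_s: float      # triangle onset

    @property
    def cue_onset_s(self) -> float:
        return self.onset_s + 0.3


@dataclass
class TaskEventPlan:
    trials: list[Trial]
    n_blocks: int
    trials_per_block: int

    def __len__(self) -> int:
        return len(self.trials)


@dataclass
class SubjectSpec:
    subject_id: str
    group: str
    cell_faa: dict            # (emotion, relevance) -> realised target
    latent_efaa: float
    scores: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# task events
# ---------------------------------------------------------------------------

def generate_task_events(seed: int, n_blocks: int = 16,
                         trials_per_block: int = 64,
                         iti_range_s: tuple[float, float] = (2.5, 3.5),
                         lead_in_s: float = 5.0) -> TaskEventPlan:
    """Build the ordered trial plan of the Go/NoGo task.

    Each of the 4 response rules governs ``n_blocks/4`` whole blocks (rules
    1–2 attend the colour cue, so the emotional figure is task-irrelevant;
    rules 3–4 attend the figure, making it relevant).  Within a block,
    emotion and go/nogo are balanced 32/32 (crossed 16 per combination at
    the default size).  Trial onsets increase by a uniform inter-trial
    interval drawn from ``iti_range_s``.
    """
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    rng = np.random.default_rng(seed)
    rules = np.repeat(np.arange(1, 5), n_blocks // 4)
    rng.shuffle(rules)

    per_combo = trials_per_block // 4
    trials: list[Trial] = []
    t = lead_in_s
    for b, rule in enumerate(rules, start=1):
        relevance = "irrelevant" if rule <= 2 else "relevant"
        combos = [(emo, resp)
                  for emo in ("threat", "neutral")
                  for resp in ("go", "nogo")] * per_combo
        rng.shuffle(combos)
        for i, (emo, resp) in enumerate(combos, start=1):
            trials.append(Trial(block=b, trial=i, rule_id=int(rule),
                                emotion=emo, relevance=relevance,
                                response=resp, onset_s=round(t, 3)))
            t += rng.uniform(*iti_range_s)
    return TaskEventPlan(trials=trials, n_blocks=n_blocks,
                         trials_per_block=trials_per_block)


# ---------------------------------------------------------------------------
# signal model
# ---------------------------------------------------------------------------

def amplitudes_for_faa(target_faa: float, base_power_f3: float
                       ) -> tuple[float, float]:
    """Alpha powers (P_F3, P_F4) in µV² realising ln(P4) − ln(P3) = target."""
    if base_power_f3 <= 0:
        raise ValueError("base power must be positive")
    return base_power_f3, base_power_f3 * math.exp(target_faa)


def _noise_band_auc(noise_rms_uv: float, lo: float = 8.0, hi: float = 12.0
                    ) -> float:
    """Alpha-band AUC ν of the generated pink noise, from its synthesis PSD.

    The noise PSD is c/f on [PINK_FLOOR_HZ, Nyquist] (flat below the
    floor), normalised so the total power is ``noise_rms_uv²``.
    """
    if noise_rms_uv == 0:
        return 0.0
    nyq = FS_HZ / 2.0
    f0 = PINK_FLOOR_HZ
    # total = c·[1 (flat part, width f0 at density c/f0 → f0·c/f0 = c·? )]
    # flat part: density c/f0 over [0, f0] → power c; 1/f part: c·ln(nyq/f0)
    total_unit = 1.0 + math.log(nyq / f0)
    c = noise_rms_uv ** 2 / total_unit
    return c * math.log(hi / lo)


def _compensated_powers(target_faa: float, base_power_f3: float,
                        noise_rms_uv: float) -> tuple[float, float]:
    """Cell powers such that the pipeline's band ratio (signal + noise)
    equals e^target in expectation.

    Re-referencing to Cz adds Cz's independent noise to every electrode, so
    the effective noise band AUC seen by the pipeline is 2ν.
    """
    nu = 2.0 * _noise_band_auc(noise_rms_uv)
    p3 = base_power_f3
    p4 = (p3 + nu) * math.exp(target_faa) - nu
    if p4 <= 0:
        raise ValueError(
            f"target FAA {target_faa} unreachable at base power {p3} µV² "
            f"with noise band AUC {nu:.3g} µV²")
    return p3, p4


def _pink_noise(rng: np.random.Generator, n: int, rms_uv: float) -> np.ndarray:
    if rms_uv == 0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / FS_HZ)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = 1.0 / np.sqrt(np.maximum(freqs[nz], PINK_FLOOR_HZ))
    shape[freqs <= 0] = 1.0 / np.sqrt(PINK_FLOOR_HZ)
    spec = shape * (rng.standard_normal(len(freqs))
                    + 1j * rng.standard_normal(len(freqs)))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    x *= rms_uv / np.sqrt(np.mean(x ** 2))
    return x


def _edge_taper(n: int, ramp_frac: float = 0.1) -> tuple[np.ndarray, float]:
    """Tukey (Hann-edged) taper and its mean-square, for amplitude
    compensation so the epoch's band AUC is unaffected by the taper."""
    from scipy.signal.windows import tukey
    w = tukey(n, alpha=ramp_frac)
    return w, float(np.mean(w ** 2))


def _blink_kernel(width_s: float = 0.3) -> np.ndarray:
    n = int(round(width_s * FS_HZ))
    return np.hanning(n)


def synthesize_recording(subject: SubjectSpec, events: TaskEventPlan,
                         spec: CohortSpec, seed: int
                         ) -> tuple[Recording, pd.DataFrame]:
    """Render one subject's continuous EEG for the given task plan.

    Returns the :class:`Recording` and a per-trial artifact log with
    columns (trial_index, blink_in_epoch, artifact_peak_uv): whether a
    blink peak falls inside the trial's 2-s analysis window, and the
    maximum absolute frontal artifact amplitude within that window after
    subtracting the artifact's own 200-ms baseline mean (i.e. as the
    rejection stage will see it).
    """
    for ch in ("F3", "F4", "Cz", "VEOG"):
        if ch not in MONTAGE:
            raise ValueError(f"montage missing required channel {ch}")
    rng = np.random.default_rng(seed)
    duration_s = events.trials[-1].onset_s + EPOCH_S + 1.0
    n = int(math.ceil(duration_s * FS_HZ))
    data = np.zeros((len(MONTAGE), n))
    ch_idx = {c: i for i, c in enumerate(MONTAGE)}

    # background pink noise, independent per channel
    for c in MONTAGE:
        data[ch_idx[c]] += _pink_noise(rng, n, spec.noise_rms_uv)

    # per-trial alpha with the condition's calibrated F3/F4 powers
    n_ep = int(EPOCH_S * FS_HZ)
    taper, taper_ms = _edge_taper(n_ep)
    t_ep = np.arange(n_ep) / FS_HZ
    markers: list[Marker] = []
    onset_samples = []
    last_block = 0
    for tr in events.trials:
        onset = int(round(tr.onset_s * FS_HZ / 2.0)) * 2  # even: survives ÷2
        onset_samples.append(onset)
        if tr.block != last_block:
            markers.append(Marker("Comment", f"block {tr.block} rule {tr.rule_id}",
                                  onset))
            last_block = tr.block
        markers.append(Marker("Stimulus",
                              encode_condition(tr.emotion, tr.relevance,
                                               tr.response),
                              onset))
        target = subject.cell_faa[(tr.emotion, tr.relevance)]
        p3, p4 = _compensated_powers(target, spec.base_power_f3,
                                     spec.noise_rms_uv)
        for ch, power in (("F3", p3), ("F4", p4)):
            amp = math.sqrt(2.0 * power / taper_ms)
            phase = rng.uniform(0, 2 * math.pi)
            wave = amp * taper * np.sin(
                2 * math.pi * spec.alpha_freq_hz * t_ep + phase)
            data[ch_idx[ch], onset:onset + n_ep] += wave

    # blinks: Poisson events on VEOG, propagated to frontal channels
    artifact = np.zeros(n)  # frontal-channel artifact contribution
    blink_centers: list[int] = []
    if spec.blink_rate_per_min > 0:
        kernel = _blink_kernel()
        half = len(kernel) // 2
        n_blinks = rng.poisson(spec.blink_rate_per_min / 60.0 * duration_s)
        centers = np.sort(rng.integers(half, n - half, size=n_blinks))
        for c in centers:
            lo, hi = c - half, c - half + len(kernel)
            data[ch_idx["VEOG"], lo:hi] += spec.blink_amplitude_uv * kernel
            bump = spec.blink_amplitude_uv * spec.blink_propagation * kernel
            for ch in ("F3", "F4", "Fz"):
                data[ch_idx[ch], lo:hi] += bump
            artifact[lo:hi] += bump
            blink_centers.append(int(c))

    # per-trial artifact log, measured the way the rejection stage will
    centers_arr = np.asarray(blink_centers)
    n_base = int(BASELINE_S * FS_HZ)
    log_rows = []
    for i, onset in enumerate(onset_samples):
        window = artifact[onset:onset + n_ep]
        base = window[:n_base].mean() if len(window) >= n_base else 0.0
        peak = float(np.max(np.abs(window - base))) if len(window) else 0.0
        in_ep = bool(
            len(centers_arr)
            and ((centers_arr >= onset) & (centers_arr < onset + n_ep)).any()
        )
        log_rows.append((i, in_ep, peak))
    log = pd.DataFrame(log_rows,
                       columns=["trial_index", "blink_in_epoch",
                                "artifact_peak_uv"])

    markers.sort(key=lambda m: m.onset_sample)
    rec = Recording(channels=list(MONTAGE), sfreq=FS_HZ, data=data,
                    markers=markers)
    return rec, log


# ---------------------------------------------------------------------------
# questionnaires via Gaussian copula
# ---------------------------------------------------------------------------

def _bdi_scale() -> float:
    # scale the Gamma(1.2) marginal so ~15% of subjects reach the
    # mild-depression cut-off of 10 points
    return 9.5 / sps.gamma.isf(0.15, a=1.2)


def _latent_pearson(rho_spearman: float) -> float:
    """Pearson correlation of the Gaussian copula that yields the requested
    Spearman correlation on continuous marginals."""
    return 2.0 * math.sin(math.pi * rho_spearman / 6.0)


def _copula_uniform(latent: np.ndarray, rho_s: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Uniforms rank-coupled to ``latent`` at Spearman target ``rho_s``."""
    n = len(latent)
    ranks = sps.rankdata(latent)
    z_e = sps.norm.ppf((ranks - 0.5) / n)
    rho = _latent_pearson(rho_s)
    z_q = rho * z_e + math.sqrt(1.0 - rho ** 2) * rng.standard_normal(n)
    return sps.norm.cdf(z_q)


def generate_questionnaires(latent_efaa: np.ndarray, groups: list[str],
                            spec: CohortSpec, seed: int) -> pd.DataFrame:
    """Questionnaire and clinical scores coupled to latent eFAA.

    Marginals: BDI and RPQ are right-skewed rounded-Gamma counts (RPQ is
    forced to 0 for NonSymp subjects, ≥ 1 for Symp); PTA (hours, < 24) and
    months post-injury exist for the mild-TBI groups only; age is drawn
    from the group's published moments.
    """
    latent_efaa = np.asarray(latent_efaa, dtype=float)
    groups_arr = np.asarray(groups)
    n = len(latent_efaa)
    # distinct stream key so a caller-shared seed never replays the stream
    # that produced the latent scores
    rng = np.random.default_rng([seed, 0x51C0])
    mtbi = groups_arr != "Control"

    out = pd.DataFrame(index=range(n))
    out["group"] = groups_arr

    u_bdi = _copula_uniform(latent_efaa, spec.coupling.get("bdi", 0.0), rng)
    out["bdi"] = np.round(sps.gamma.ppf(u_bdi, a=1.2,
                                        scale=_bdi_scale())).astype(int)

    u_rpq = _copula_uniform(latent_efaa, spec.coupling.get("rpq", 0.0), rng)
    rpq = np.zeros(n, dtype=int)
    symp = groups_arr == "Symp"
    ctrl = groups_arr == "Control"
    rpq[symp] = 1 + np.round(sps.gamma.ppf(u_rpq[symp], a=1.3,
                                           scale=4.0)).astype(int)
    rpq[ctrl] = np.round(sps.gamma.ppf(u_rpq[ctrl], a=0.8,
                                       scale=2.0)).astype(int)
    out["rpq"] = rpq  # NonSymp stays 0 by definition of the group
    out["rpq_emotional"] = rng.binomial(rpq, 0.3)

    out["brief_gec"] = np.clip(np.round(rng.normal(50, 10, n)), 30, 90
                               ).astype(int)
    out["brief_ec"] = np.clip(np.round(rng.normal(50, 10, n)), 30, 90
                              ).astype(int)

    age = np.empty(n)
    for g, (mu, sd) in reference.AGE.items():
        mask = groups_arr == g
        age[mask] = rng.normal(mu, sd, mask.sum())
    out["age"] = np.clip(np.round(age, 1), 18.0, 65.0)

    pta = np.full(n, np.nan)
    u_pta = _copula_uniform(latent_efaa,
                            spec.coupling.get("pta_hours", 0.0), rng)
    pta[mtbi] = np.clip(np.round(sps.gamma.ppf(u_pta[mtbi], a=1.0,
                                               scale=4.0), 1), 0.0, 23.9)
    out["pta_hours"] = pta

    mpi = np.full(n, np.nan)
    mu, sd, lo, hi = reference.MONTHS_POST_INJURY
    mpi[mtbi] = np.clip(np.round(rng.normal(mu, sd, mtbi.sum()), 1), lo, hi)
    out["months_post_injury"] = mpi
    return out


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _subject_specs(spec: CohortSpec, rng: np.random.Generator
                   ) -> list[SubjectSpec]:
    subjects: list[SubjectSpec] = []
    prefix = {"Control": "C", "NonSymp": "N", "Symp": "S"}
    for group, size in spec.group_sizes.items():
        for i in range(1, size + 1):
            b = rng.normal(0.0, spec.faa_subject_sd)
            e = rng.normal(0.0, spec.efaa_subject_sd)
            cells = {}
            for (emo, rel), target in spec.group_faa[group].items():
                sign = 0.5 if emo == "threat" else -0.5
                cells[(emo, rel)] = (target + b + sign * e
                                     + rng.normal(0.0, spec.cell_jitter_sd))
            efaa = float(np.mean(
                [cells[("threat", rel)] - cells[("neutral", rel)]
                 for rel in ("relevant", "irrelevant")]))
            subjects.append(SubjectSpec(
                subject_id=f"{prefix[group]}{i:02d}", group=group,
                cell_faa=cells, latent_efaa=efaa))
    return subjects


def ground_truth_frame(subjects: list[SubjectSpec]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        row = {"subject_id": s.subject_id, "group": s.group}
        for (emo, rel), v in s.cell_faa.items():
            row[f"faa_{emo}_{rel}"] = v
        row["faa_overall"] = float(np.mean(list(s.cell_faa.values())))
        row["latent_efaa"] = s.latent_efaa
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_scores_frame(spec: CohortSpec) -> pd.DataFrame:
    """Fast path: per-subject FAA/eFAA scores and questionnaires straight
    from the latent model, without EEG synthesis.

    The returned frame has the same layout as
    :func:`efaa.asymmetry.subject_scores` output merged with the scores
    table, so the statistical battery runs on it directly.  Used for
    calibration studies where thousands of cohorts are needed.
    """
    rng = np.random.default_rng(spec.seed)
    subjects = _subject_specs(spec, rng)
    gt = ground_truth_frame(subjects)
    q = generate_questionnaires(
        gt["latent_efaa"].to_numpy(), [s.group for s in subjects], spec,
        seed=int(rng.integers(2 ** 31)))
    df = gt.copy()
    for emo in ("threat", "neutral"):
        df[f"faa_{emo}"] = df[[f"faa_{emo}_relevant",
                               f"faa_{emo}_irrelevant"]].mean(axis=1)
    for rel in ("relevant", "irrelevant"):
        df[f"efaa_{rel}"] = (df[f"faa_threat_{rel}"]
                             - df[f"faa_neutral_{rel}"])
    df["efaa"] = df["latent_efaa"]
    for col in q.columns:
        if col != "group":
            df[col] = q[col].to_numpy()
    return df


def generate_cohort(spec: CohortSpec):
    """Generate the full cohort: one (Recording, artifact log) per subject,
    a scores table and a ground-truth table.

    Returns ``(recordings, scores, ground_truth)`` where ``recordings`` is
    an ordered dict subject_id → (Recording, artifact log DataFrame).
    Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    subjects = _subject_specs(spec, rng)
    gt = ground_truth_frame(subjects)
    q = generate_questionnaires(
        gt["latent_efaa"].to_numpy(), [s.group for s in subjects], spec,
        seed=int(rng.integers(2 ** 31)))
    scores = pd.concat(
        [gt[["subject_id", "group"]].reset_index(drop=True),
         q.drop(columns=["group"]).reset_index(drop=True)], axis=1)

    recordings: dict[str, tuple[Recording, pd.DataFrame]] = {}
    for s in subjects:
        ev_seed = int(rng.integers(2 ** 31))
        sig_seed = int(rng.integers(2 ** 31))
        events = generate_task_events(ev_seed, n_blocks=spec.n_blocks,
                                      trials_per_block=spec.trials_per_block,
                                      iti_range_s=spec.iti_range_s)
        recordings[s.subject_id] = synthesize_recording(s, events, spec,
                                                        sig_seed)
    return recordings, scores, gt


def null_spec(**overrides) -> CohortSpec:
    """A cohort spec with every group/condition effect and coupling zeroed
    (subject-level variability retained) — the null hypothesis world."""
    flat = {g: {(emo, rel): 0.0 for emo in ("threat", "neutral")
                for rel in ("relevant", "irrelevant")}
            for g in reference.GROUP_SIZES}
    base = CohortSpec(group_faa=flat,
                      coupling={"bdi": 0.0, "rpq": 0.0, "pta_hours": 0.0})
    return replace(base, **overrides) if overrides else base
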