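"""Synthetic beat-annotated single-lead ECG generator.

Emits 10-second records with per-beat class labels in {N, S, V} and
P/QRS/T segment boundaries. The generator is not meant to be
physiologically faithful; it reproduces the statistical contrasts a beat
classifier relies on:

* **V** (ventricular ectopic): widened QRS, absent P wave.
* **S** (supraventricular ectopic): premature — the RR interval preceding
  the beat is shortened by a configurable fraction.
* **N** (normal): regular P-QRS-T morphology at the mean RR.

Waveforms are sums of segment templates (Gaussian bumps for P and T, a
sharp biphasic difference-of-Gaussians for QRS) plus white noise. Every
record is fully reproducible from one seed: a global seed spawns
per-patient child seeds, so any patient subset regenerates identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

CLASSES = ("N", "S", "V")
SEGMENT_TYPES = ("P", "QRS", "T")

#: Reported N/S/V shares of the private study data (75.0/15.2/10.4 %),
#: normalized to sum to one.
_raw_mix = np.array([0.750, 0.152, 0.104])
STUDY_MIX: tuple[float, float, float] = tuple(_raw_mix / _raw_mix.sum())

RECORD_SECONDS = 10.0
_LEAD_IN = 0.35  # time before the first R peak, leaves room for its P wave
_MIN_GAP = 0.01  # minimum silence between consecutive beats' segments, s


class PatternError(ValueError):
    """Raised for an empty beat pattern or characters outside {N,S,V}."""


@dataclass(frozen=True)
class MorphologyConfig:
    """Shape and rhythm parameters of the synthetic ECG.

    Durations and times are in seconds, amplitudes in arbitrary mV-like
    units. ``s_prematurity`` is the fraction by which an S beat shortens
    its preceding RR interval; ``v_qrs_widen`` multiplies the QRS duration
    of V beats and must exceed 1.
    """

    fs: float = 250.0
    mean_rr: float = 0.8
    rr_jitter: float = 0.04        # fractional sd of RR intervals
    s_prematurity: float = 0.35
    v_qrs_widen: float = 1.9
    p_noP: float = 1.0             # probability a V beat has no P annotation
    p_dur: float = 0.09
    p_amp: float = 0.15
    qrs_dur: float = 0.10
    qrs_amp: float = 1.0
    t_dur: float = 0.16
    t_amp: float = 0.30
    pr_gap: float = 0.06           # P offset -> QRS onset
    st_gap: float = 0.05           # QRS offset -> T onset
    width_jitter: float = 0.05     # fractional sd on segment durations
    noise_sd: float = 0.03

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not 0 < self.s_prematurity < 1:
            raise ValueError("s_prematurity must lie in (0, 1)")
        if self.v_qrs_widen <= 1:
            raise ValueError("v_qrs_widen must exceed 1")


@dataclass(frozen=True)
class BeatSchedule:
    """Planned beats of one record: classes, R times, segment bounds (s)."""

    beat_classes: tuple[str, ...]
    r_times: np.ndarray
    segment_bounds: tuple[dict, ...]  # per beat: {"P"|"QRS"|"T": (onset, offset)}


@dataclass(frozen=True)
class Beat:
    label: str
    segments: dict[str, tuple[int, int]]  # 0-based half-open sample ranges

    @property
    def qrs(self) -> tuple[int, int]:
        return self.segments["QRS"]


@dataclass(frozen=True)
class AnnotatedECGRecord:
    patient_id: str
    record_id: str
    fs: float
    samples: np.ndarray
    beats: tuple[Beat, ...] = field(default_factory=tuple)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(b.label for b in self.beats)


def _beat_geometry(label: str, r: float, morph: MorphologyConfig,
                   rng: np.random.Generator) -> dict[str, tuple[float, float]]:
    """Segment (onset, offset) seconds for one beat with R peak at ``r``."""
    jit = lambda d: d * max(0.3, 1.0 + rng.normal(0.0, morph.width_jitter))
    qrs_dur = jit(morph.qrs_dur * (morph.v_qrs_widen if label == "V" else 1.0))
    p_dur = jit(morph.p_dur)
    t_dur = jit(morph.t_dur)
    qrs = (r - qrs_dur / 2, r + qrs_dur / 2)
    bounds = {"QRS": qrs}
    has_p = label != "V" or rng.random() >= morph.p_noP
    if has_p:
        bounds["P"] = (qrs[0] - morph.pr_gap - p_dur, qrs[0] - morph.pr_gap)
    bounds["T"] = (qrs[1] + morph.st_gap, qrs[1] + morph.st_gap + t_dur)
    return bounds


def generate_beat_schedule(pattern: str, morph: MorphologyConfig,
                           rng: np.random.Generator,
                           max_retries: int = 10) -> BeatSchedule:
    """Schedule one beat per pattern character inside a 10-second record.

    S beats shorten their preceding RR by ``morph.s_prematurity``; beats
    that would not complete (T offset past 10 s) are truncated. Consecutive
    beats whose segments would collide after jitter are re-drawn up to
    ``max_retries`` times, then rejected.
    """
    if not pattern:
        raise PatternError("beat pattern must be non-empty")
    bad = set(pattern) - set(CLASSES)
    if bad:
        raise PatternError(f"invalid beat classes in pattern: {sorted(bad)}")

    classes: list[str] = []
    r_times: list[float] = []
    bounds: list[dict] = []
    t = _LEAD_IN
    for label in pattern:
        for attempt in range(max_retries + 1):
            if not r_times:
                r = t
            else:
                base = morph.mean_rr
                if label == "S":
                    base *= 1.0 - morph.s_prematurity
                rr = base * max(0.4, 1.0 + rng.normal(0.0, morph.rr_jitter))
                r = r_times[-1] + rr
            geo = _beat_geometry(label, r, morph, rng)
            onset = min(lo for lo, _ in geo.values())
            prev_end = max(hi for _, hi in bounds[-1].values()) if r_times else -np.inf
            if onset >= prev_end + _MIN_GAP:
                break
            if attempt == max_retries:
                # a strongly premature beat's P may ride on the previous T;
                # clamp the encroaching onset rather than reject the pattern
                first = min(geo, key=lambda s: geo[s][0])
                lo, hi = geo[first]
                clamped = prev_end + _MIN_GAP
                if clamped < hi - 0.02:
                    geo[first] = (clamped, hi)
                elif first == "P":
                    # P wave fully buried in the previous T: annotate no P
                    del geo["P"]
                onset = min(lo for lo, _ in geo.values())
                if onset < prev_end + _MIN_GAP:
                    # a very premature beat cuts the previous T short
                    last = max(bounds[-1], key=lambda s: bounds[-1][s][1])
                    plo, phi = bounds[-1][last]
                    trimmed = onset - _MIN_GAP
                    if trimmed < plo + 0.02:
                        raise ValueError(
                            f"could not place beat {len(r_times)} without "
                            "segment collision"
                        )
                    bounds[-1][last] = (plo, trimmed)
        if max(hi for _, hi in geo.values()) > RECORD_SECONDS or onset < 0:
            break  # truncate to complete beats
        classes.append(label)
        r_times.append(r)
        bounds.append(geo)
    return BeatSchedule(tuple(classes), np.asarray(r_times), tuple(bounds))


def render_record(schedule: BeatSchedule, morph: MorphologyConfig,
                  rng: np.random.Generator, patient_id: str = "p0",
                  record_id: str = "r0") -> AnnotatedECGRecord:
    """Synthesize the waveform for a schedule and attach sample-index annotations."""
    n = int(round(RECORD_SECONDS * morph.fs))
    samples = rng.normal(0.0, morph.noise_sd, size=n)
    tgrid = np.arange(n) / morph.fs
    beats: list[Beat] = []
    for label, geo in zip(schedule.beat_classes, schedule.segment_bounds):
        segs: dict[str, tuple[int, int]] = {}
        for stype, (lo, hi) in sorted(geo.items(), key=lambda kv: kv[1][0]):
            i0 = max(0, int(round(lo * morph.fs)))
            i1 = min(n, int(round(hi * morph.fs)))
            if i1 <= i0:
                continue
            center = (lo + hi) / 2
            dur = hi - lo
            x = tgrid[i0:i1]
            if stype == "QRS":
                s = dur / 10.0
                wave = morph.qrs_amp * (
                    np.exp(-0.5 * ((x - center + dur / 12) / s) ** 2)
                    - 0.55 * np.exp(-0.5 * ((x - center - dur / 6) / s) ** 2)
                )
            else:
                amp = morph.p_amp if stype == "P" else morph.t_amp
                wave = amp * np.exp(-0.5 * ((x - center) / (dur / 6.0)) ** 2)
            samples[i0:i1] += wave
            segs[stype] = (i0, i1)
        beats.append(Beat(label, segs))
    return AnnotatedECGRecord(patient_id, record_id, morph.fs, samples, tuple(beats))


def generate_record(pattern: str, morph: MorphologyConfig, rng: np.random.Generator,
                    patient_id: str = "p0", record_id: str = "r0") -> AnnotatedECGRecord:
    schedule = generate_beat_schedule(pattern, morph, rng)
    return render_record(schedule, morph, rng, patient_id, record_id)


def _quota_pattern(n_beats: int, class_mix: Sequence[float],
                   rng: np.random.Generator) -> str:
    """Random beat-class arrangement whose counts follow ``class_mix`` quotas.

    Counts are the largest-remainder apportionment of ``class_mix * n_beats``
    with the leftover slots assigned at random in proportion to the
    fractional parts, so realized dataset-level proportions stay within a
    fraction of a percentage point of the requested mixture.
    """
    mix = np.asarray(class_mix, dtype=float)
    if mix.min() < 0 or not np.isclose(mix.sum(), 1.0, atol=1e-6):
        raise ValueError("class_mix must be non-negative and sum to 1")
    exact = mix * n_beats
    counts = np.floor(exact).astype(int)
    frac = exact - counts
    for _ in range(n_beats - counts.sum()):
        p = np.where(frac > 0, frac, 1e-12)
        idx = rng.choice(3, p=p / p.sum())
        counts[idx] += 1
        frac[idx] = 0.0
    labels = [c for c, k in zip(CLASSES, counts) for _ in range(k)]
    rng.shuffle(labels)
    return "".join(labels)


def _planned_beats(morph: MorphologyConfig) -> int:
    usable = RECORD_SECONDS - _LEAD_IN - (morph.qrs_dur / 2 + morph.st_gap + morph.t_dur)
    return max(1, int(usable / morph.mean_rr) + 1)


def patient_seeds(seed: int, n_patients: int) -> list[np.random.SeedSequence]:
    """Per-patient child seeds (splitmix-style spawn of one global seed)."""
    return np.random.SeedSequence(seed).spawn(n_patients)


def generate_dataset(n_patients: int, records_per_patient: int,
                     class_mix: Sequence[float] = STUDY_MIX,
                     seed: int = 0, morph: MorphologyConfig | None = None,
                     pattern: str | None = None,
                     patient_rr_range: tuple[float, float] | None = (0.65, 1.05),
                     ) -> list[AnnotatedECGRecord]:
    """Generate ``n_patients × records_per_patient`` annotated records.

    With ``pattern`` given, every record realizes exactly that beat string;
    otherwise beat classes follow ``class_mix`` via per-record quotas.
    ``patient_rr_range`` draws each patient's resting RR uniformly from the
    given interval (seconds), emulating inter-patient heart-rate variability:
    a premature beat is then premature relative to its owner's rhythm, not
    to any absolute interval. Pass ``None`` to give every patient
    ``morph.mean_rr``. Identical arguments produce identical datasets.
    """
    morph = morph or MorphologyConfig()
    records: list[AnnotatedECGRecord] = []
    for p, ss in enumerate(patient_seeds(seed, n_patients)):
        rng = np.random.default_rng(ss)
        pmorph = morph
        if patient_rr_range is not None:
            pmorph = replace(morph, mean_rr=float(rng.uniform(*patient_rr_range)))
        for r in range(records_per_patient):
            pat = pattern or _quota_pattern(_planned_beats(pmorph), class_mix, rng)
            records.append(
                generate_record(pat, pmorph, rng, patient_id=f"p{p:03d}",
                                record_id=f"r{r:03d}")
            )
    return records


def strong_contrast_morphology() -> MorphologyConfig:
    """Morphology with pronounced class contrasts, used as the benchmark
    regime for end-to-end learning experiments: strongly widened V QRS
    (×2.2), strong S prematurity (45 %), low rhythm jitter and noise."""
    return MorphologyConfig(v_qrs_widen=2.2, s_prematurity=0.45,
                            rr_jitter=0.03, noise_sd=0.03)


def has_ectopic_run(labels: Sequence[str], min_run: int = 4) -> bool:
    """True if ``labels`` contains >= ``min_run`` consecutive beats of one
    ectopic class (all S or all V)."""
    run, prev = 0, None
    for lab in labels:
        if lab in ("S", "V") and lab == prev:
            run += 1
        elif lab in ("S", "V"):
            run, prev = 1, lab
        else:
            run, prev = 0, None
        if run >= min_run:
            return True
    return False


PATTERN_TEMPLATES = (
    "NNNNSSSS", "NNNVVVVN", "SSSSNNNN", "NVVVVNNN",
    "NNSSSSNN", "VVVVNNNN", "NSSSSSNN", "NNNNVVVV",
)


def generate_scalability_dataset(
    n_train_patients: int = 20,
    n_test_patients: int = 8,
    seed: int = 0,
    class_mix: Sequence[float] = (0.72, 0.16, 0.12),
    morph: MorphologyConfig | None = None,
    records_per_train_patient: int = 6,
    patient_rr_range: tuple[float, float] = (0.70, 1.10),
) -> list[AnnotatedECGRecord]:
    """Dataset for the pattern/size generalization protocol.

    Training-side patients carry only 8-beat records with mixed beat
    arrangements that never contain a run of >= 4 consecutive same-class
    ectopic beats. Test-side patients carry, each: two 8-beat records with
    such runs (e.g. NNNNSSSS), two mixed 8-beat records (control), and two
    full 10-second records of >= 9 beats (size) at the patient's own
    rhythm. Every patient's resting RR is drawn from ``patient_rr_range``
    so training covers the rhythm spectrum the size records realize. Which
    patients end up on which side is decided downstream purely by the run
    rule, not by this layout.
    """
    base = morph or MorphologyConfig(rr_jitter=0.03)
    records: list[AnnotatedECGRecord] = []
    n_total = n_train_patients + n_test_patients
    for p, ss in enumerate(patient_seeds(seed, n_total)):
        rng = np.random.default_rng(ss)
        pmorph = replace(base, mean_rr=float(rng.uniform(*patient_rr_range)))
        pid = f"p{p:03d}"
        is_test = p >= n_train_patients
        rid = 0
        if is_test:
            for _ in range(2):
                pat = PATTERN_TEMPLATES[rng.integers(len(PATTERN_TEMPLATES))]
                records.append(generate_record(pat, pmorph, rng, pid, f"r{rid:03d}"))
                rid += 1
            for _ in range(2):  # control: mixed 8-beat
                pat = _mixed_pattern(8, class_mix, rng)
                records.append(generate_record(pat, pmorph, rng, pid, f"r{rid:03d}"))
                rid += 1
            for _ in range(2):  # size: as many beats as fit, >= 9
                pat = _mixed_pattern(max(9, _planned_beats(pmorph)), class_mix, rng)
                rec = generate_record(pat, pmorph, rng, pid, f"r{rid:03d}")
                if len(rec.beats) >= 9:
                    records.append(rec)
                    rid += 1
        else:
            for _ in range(records_per_train_patient):
                pat = _mixed_pattern(8, class_mix, rng)
                records.append(generate_record(pat, pmorph, rng, pid, f"r{rid:03d}"))
                rid += 1
    return records


def _mixed_pattern(n_beats: int, class_mix: Sequence[float],
                   rng: np.random.Generator, max_tries: int = 50) -> str:
    """Quota pattern rejected until it contains no >=4-run of one ectopic class."""
    for _ in range(max_tries):
        pat = _quota_pattern(n_beats, class_mix, rng)
        if not has_ectopic_run(pat):
            return pat
    raise RuntimeError("could not draw a pattern without an ectopic run")
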