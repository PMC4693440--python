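"""Synthetic cohorts of simulated patch-clamp cells and family variant sets.

Stands in for the experimental datasets: whole-cell T-type calcium currents
recorded from cells expressing wild-type or p.Arg1715His-mutant Cav3.1, and
exome variant tables of a dominant spinocerebellar-ataxia family.

Per-cell gating parameters are drawn from group distributions whose means and
SDs are the published group summaries (wild-type n = 9, mutant n = 12); every
recording stores its ground-truth parameters so recovery can be scored.
Two synthesis modes exist:

* ``kinetic`` — full step-response simulation of the gating model plus
  additive Gaussian recording noise (optional 3 kHz low-pass);
* ``idealized`` — per-sweep peak currents placed analytically at
  g_max * m_inf(V)**p * h_inf(prepulse) * (V - E_rev) under a stereotyped
  rise/decay envelope, so peak extraction recovers them exactly.  This mode
  isolates the analysis chain from kinetic distortion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .channel_model import (
    GatingParams,
    simulate_step_response,
    steady_state_activation,
    steady_state_inactivation,
)
from .protocols import VoltageProtocol, activation_protocol, inactivation_protocol
from .variant_filter import (
    PedigreeSample,
    VariantRecord,
    funnel_filter,
    prediction_consensus,
)

__all__ = [
    "GroupSpec",
    "CellRecording",
    "wt_group_spec",
    "mutant_group_spec",
    "sample_cell_params",
    "generate_recording",
    "generate_cohort",
    "CausalSpec",
    "demo_pedigree",
    "generate_variant_fixture",
]

# idealized-mode envelope: (1 - exp(-t/RISE)) * exp(-t/DECAY), peaking ~6.7 ms
# after step onset — safely beyond the default 2 ms blanking window
_ENVELOPE_RISE_MS = 3.0
_ENVELOPE_DECAY_MS = 25.0


@dataclass(frozen=True)
class GroupSpec:
    """Distributional description of one expression group (mean, SD per
    gating parameter, all in mV except g_max in nS)."""

    label: str
    n_cells: int
    v_half_act: tuple[float, float]
    k_act: tuple[float, float]
    v_half_inact: tuple[float, float]
    k_inact: tuple[float, float]
    g_max: tuple[float, float] = (5.0, 1.5)
    e_rev: tuple[float, float] = (45.0, 3.0)

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in ("v_half_act", "k_act", "v_half_inact", "k_inact", "g_max", "e_rev"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"{name} SD must be >= 0, got {sd}")

    def mean_params(self) -> GatingParams:
        return GatingParams(
            g_max=self.g_max[0],
            e_rev=self.e_rev[0],
            v_half_act=self.v_half_act[0],
            k_act=self.k_act[0],
            v_half_inact=self.v_half_inact[0],
            k_inact=self.k_inact[0],
        )


def wt_group_spec(n_cells: int = 9) -> GroupSpec:
    """Wild-type group at the published means/SDs."""
    return GroupSpec(
        label="WT",
        n_cells=n_cells,
        v_half_act=(-57.5, 9.1),
        k_act=(6.4, 2.2),
        v_half_inact=(-79.1, 6.6),
        k_inact=(6.3, 1.4),
    )


def mutant_group_spec(n_cells: int = 12) -> GroupSpec:
    """p.Arg1715His mutant group at the published means/SDs."""
    return GroupSpec(
        label="mutant",
        n_cells=n_cells,
        v_half_act=(-44.7, 6.0),
        k_act=(6.2, 2.9),
        v_half_inact=(-72.5, 5.5),
        k_inact=(7.7, 1.5),
    )


_K_FLOOR_MV = 0.5  # slope factors truncated to stay physically meaningful


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _draw_truncated(rng, mean, sd, lower):
    if sd == 0:
        if mean <= lower:
            raise ValueError(f"degenerate draw: mean {mean} at or below bound {lower} with SD 0")
        return mean
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if x > lower:
            return x
    raise ValueError(f"truncation rejected 10000 draws (mean {mean}, SD {sd}, bound {lower})")


def sample_cell_params(spec: GroupSpec, rng_seed) -> GatingParams:
    """Draw one cell's gating parameters: independent normals per parameter,
    truncated to k > 0.5 mV and g_max > 0.  Deterministic given the seed."""
    rng = _as_rng(rng_seed)
    return GatingParams(
        g_max=_draw_truncated(rng, *spec.g_max, lower=0.0),
        e_rev=rng.normal(*spec.e_rev) if spec.e_rev[1] > 0 else spec.e_rev[0],
        v_half_act=rng.normal(*spec.v_half_act) if spec.v_half_act[1] > 0 else spec.v_half_act[0],
        k_act=_draw_truncated(rng, *spec.k_act, lower=_K_FLOOR_MV),
        v_half_inact=(
            rng.normal(*spec.v_half_inact) if spec.v_half_inact[1] > 0 else spec.v_half_inact[0]
        ),
        k_inact=_draw_truncated(rng, *spec.k_inact, lower=_K_FLOOR_MV),
    )


@dataclass
class CellRecording:
    """Sweep sets for both protocols plus the generating ground truth."""

    cell_id: str
    group: str
    truth: GatingParams
    act_protocol: VoltageProtocol
    inact_protocol: VoltageProtocol
    activation_sweeps: pd.DataFrame
    inactivation_sweeps: pd.DataFrame
    noise_sd: float
    mode: str
    seed: int | None = None


def _idealized_sweeps(p: GatingParams, protocol: VoltageProtocol) -> pd.DataFrame:
    """Place exact analytic peaks under a stereotyped envelope.

    The envelope is normalized by its maximum over the actual sample grid, so
    the sampled extremum equals the analytic peak to machine precision.
    Current is zero outside the measured (last) segment.
    """
    dt_ms = 1000.0 / protocol.sampling_rate_hz
    frames = []
    measure_idx = len(protocol.segments) - 1
    for sweep_id in range(protocol.n_sweeps):
        segments = protocol.sweep_segments(sweep_id)
        prepulse_v = segments[measure_idx - 1].level_mv if measure_idx > 0 else segments[0].level_mv
        step_v = segments[measure_idx].level_mv
        peak = (
            p.g_max
            * float(steady_state_activation(step_v, p)) ** p.act_exponent
            * float(steady_state_inactivation(prepulse_v, p))
            * (step_v - p.e_rev)
        )
        times, volts, currents = [], [], []
        t_offset = 0.0
        for i, seg in enumerate(segments):
            n = protocol.segment_sample_count(seg)
            t_local = np.arange(n) * dt_ms
            if i == measure_idx:
                env = (1.0 - np.exp(-t_local / _ENVELOPE_RISE_MS)) * np.exp(
                    -t_local / _ENVELOPE_DECAY_MS
                )
                env /= env.max()
                cur = peak * env
            else:
                cur = np.zeros(n)
            times.append(t_local + t_offset)
            volts.append(np.full(n, seg.level_mv))
            currents.append(cur)
            t_offset += seg.duration_ms
        frames.append(
            pd.DataFrame(
                {
                    "sweep_id": sweep_id,
                    "time_ms": np.concatenate(times),
                    "voltage_mV": np.concatenate(volts),
                    "current_pA": np.concatenate(currents),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _lowpass_3khz(current: np.ndarray, rate_hz: float) -> np.ndarray:
    from scipy.signal import butter, filtfilt

    b, a = butter(4, 3000.0, btype="low", fs=rate_hz)
    return filtfilt(b, a, current)


def generate_recording(
    p: GatingParams,
    act_protocol: VoltageProtocol | None = None,
    inact_protocol: VoltageProtocol | None = None,
    noise_sd: float = 5.0,
    mode: str = "kinetic",
    rng_seed=None,
    filter_3khz: bool = False,
    cell_id: str = "cell",
    group: str = "",
) -> CellRecording:
    """Synthesize one cell's activation and inactivation sweep sets.

    ``noise_sd`` is the SD (pA) of additive white Gaussian recording noise;
    with ``filter_3khz`` the noisy trace is low-passed with a 4th-order
    Butterworth at 3 kHz (zero-phase), mirroring hardware anti-alias
    filtering.  Deterministic given ``rng_seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if mode not in ("idealized", "kinetic"):
        raise ValueError(f"unknown mode {mode!r}; expected 'idealized' or 'kinetic'")
    if act_protocol is None:
        act_protocol = activation_protocol()
    if inact_protocol is None:
        inact_protocol = inactivation_protocol(sampling_rate_hz=act_protocol.sampling_rate_hz)
    rng = _as_rng(rng_seed)
    synth = _idealized_sweeps if mode == "idealized" else simulate_step_response
    sweep_sets = []
    for protocol in (act_protocol, inact_protocol):
        df = synth(p, protocol)
        if noise_sd > 0:
            current = df["current_pA"].to_numpy() + rng.normal(0.0, noise_sd, size=len(df))
            if filter_3khz and act_protocol.sampling_rate_hz > 6000.0:
                out = np.empty_like(current)
                for sweep_id, idx in df.groupby("sweep_id").indices.items():
                    out[idx] = _lowpass_3khz(current[idx], protocol.sampling_rate_hz)
                current = out
            df = df.assign(current_pA=current)
        sweep_sets.append(df)
    return CellRecording(
        cell_id=cell_id,
        group=group,
        truth=p,
        act_protocol=act_protocol,
        inact_protocol=inact_protocol,
        activation_sweeps=sweep_sets[0],
        inactivation_sweeps=sweep_sets[1],
        noise_sd=noise_sd,
        mode=mode,
        seed=rng_seed if isinstance(rng_seed, (int, np.integer)) else None,
    )


def generate_cohort(
    wt: GroupSpec | None = None,
    mut: GroupSpec | None = None,
    master_seed: int = 0,
    mode: str = "kinetic",
    noise_sd: float = 5.0,
    act_protocol: VoltageProtocol | None = None,
    inact_protocol: VoltageProtocol | None = None,
    filter_3khz: bool = False,
) -> list:
    """Generate the two-group cohort (default 9 WT + 12 mutant cells).

    Per-cell seeds are derived deterministically from ``master_seed`` and the
    cell index, so the same master seed reproduces the cohort bit-for-bit.
    """
    if wt is None:
        wt = wt_group_spec()
    if mut is None:
        mut = mutant_group_spec()
    seed_rng = np.random.default_rng(master_seed)
    cohort = []
    for spec in (wt, mut):
        for i in range(spec.n_cells):
            cell_seed = int(seed_rng.integers(0, 2**31 - 1))
            rng = np.random.default_rng(cell_seed)
            params = sample_cell_params(spec, rng)
            rec = generate_recording(
                params,
                act_protocol=act_protocol,
                inact_protocol=inact_protocol,
                noise_sd=noise_sd,
                mode=mode,
                rng_seed=rng,
                filter_3khz=filter_3khz,
                cell_id=f"{spec.label}-{i:02d}",
                group=spec.label,
            )
            rec.seed = cell_seed
            cohort.append(rec)
    return cohort


# ---------------------------------------------------------------------------
# family variant fixture


@dataclass(frozen=True)
class CausalSpec:
    """Description of the planted fully-segregating pathogenic variant."""

    chrom: str = "17"
    pos: int = 48_694_921
    ref: str = "G"
    alt: str = "A"
    gene: str = "CACNA1G"
    prediction_calls: tuple = ("damaging", "damaging", "damaging")


def demo_pedigree() -> list:
    """A three-generation dominant family: 3 sequenced affected, 2 unaffected,
    2 unknown-status young members (possible pre-symptomatic carriers)."""
    fam = "FAM1"
    return [
        PedigreeSample(fam, "III-1", "0", "0", 1, "affected"),
        PedigreeSample(fam, "III-2", "0", "0", 2, "unaffected"),
        PedigreeSample(fam, "III-3", "0", "0", 2, "affected"),
        PedigreeSample(fam, "III-4", "0", "0", 1, "unaffected"),
        PedigreeSample(fam, "III-5", "0", "0", 1, "affected"),
        PedigreeSample(fam, "IV-1", "III-1", "0", 2, "unknown"),
        PedigreeSample(fam, "IV-2", "III-3", "0", 1, "unknown"),
    ]


_FUNCTION_CLASSES = (
    "exonic-nonsynonymous",
    "exonic-synonymous",
    "intronic",
    "intergenic",
    "splicing",
    "UTR",
)


def generate_variant_fixture(
    n_variants: int = 200,
    pedigree=None,
    causal_spec: CausalSpec | None = None,
    rng_seed=None,
):
    """Emit an annotated family variant table with one planted causal variant.

    Decoy variants get random annotations (database flags ~ typical exome
    rates, mixed function classes, random genotypes and prediction calls);
    any decoy that would survive the full funnel *and* the 2-of-3 consensus
    is pushed into dbSNP so the planted variant is by construction the unique
    survivor when ``causal_spec`` is given.

    Returns ``(variants, pedigree)``.
    """
    rng = _as_rng(rng_seed)
    if pedigree is None:
        pedigree = demo_pedigree()
    affected = [p.sample_id for p in pedigree if p.status == "affected"]
    unaffected = [p.sample_id for p in pedigree if p.status == "unaffected"]
    unknowns = [p.sample_id for p in pedigree if p.status == "unknown"]
    if not affected or not unaffected:
        raise ValueError("pedigree needs at least one affected and one unaffected member")
    sample_ids = [p.sample_id for p in pedigree]

    variants = []
    positions = np.sort(rng.choice(np.arange(1, 10**8), size=n_variants, replace=False))
    for i in range(n_variants):
        genotypes = {
            s: rng.choice(["ref", "het", "hom"], p=[0.55, 0.35, 0.10]) for s in sample_ids
        }
        v = VariantRecord(
            chrom=str(rng.integers(1, 23)),
            pos=int(positions[i]),
            ref=str(rng.choice(list("ACGT"))),
            alt=str(rng.choice(list("ACGT"))),
            gene=f"GENE{i:04d}",
            function_class=str(rng.choice(_FUNCTION_CLASSES)),
            in_dbsnp=bool(rng.random() < 0.80),
            in_1000g=bool(rng.random() < 0.60),
            in_esp=bool(rng.random() < 0.50),
            in_inhouse=bool(rng.random() < 0.15),
            genotypes=genotypes,
            prediction_calls=tuple(
                rng.choice(["damaging", "benign", "unknown"], p=[0.3, 0.5, 0.2]) for _ in range(3)
            ),
        )
        if (
            causal_spec is not None
            and len(funnel_filter([v], affected).survivors) == 1
            and prediction_consensus(v)
        ):
            v.in_dbsnp = True
        variants.append(v)

    if causal_spec is not None:
        genotypes = {s: "het" for s in affected}
        genotypes.update({s: "ref" for s in unaffected})
        genotypes.update({s: "het" for s in unknowns})
        causal = VariantRecord(
            chrom=causal_spec.chrom,
            pos=causal_spec.pos,
            ref=causal_spec.ref,
            alt=causal_spec.alt,
            gene=causal_spec.gene,
            function_class="exonic-nonsynonymous",
            in_dbsnp=False,
            in_1000g=False,
            in_esp=False,
            in_inhouse=False,
            genotypes=genotypes,
            prediction_calls=causal_spec.prediction_calls,
        )
        variants.append(causal)
        variants.sort(key=lambda v: (v.chrom, v.pos))
    return variants, pedigree
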