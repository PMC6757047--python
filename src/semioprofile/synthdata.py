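"""Synthetic study generator for odour-profile pipelines.

Emulates a repeated-measures scent-sampling study: a dozen females sampled
across ovarian-cycle phases (follicular / peri-ovulatory / luteal) over one
to three cycles each, plus handling and room-air blanks.  Latent substance
intensities follow a log-normal model whose fixed and random terms mirror the
downstream mixed model (cycle, age, parity, genital side, ultrasound timing,
assistant presence; female, batch and residual noise), so that planted
effects are exactly recoverable by the statistical screen and form the
ground truth for every test in the package.

The generator does no chromatographic physics: rendered peaks are point
events with Gaussian retention-time jitter and Bernoulli dropout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ContaminantEntry, Peak, PeakList

__all__ = [
    "CYCLE_STATES",
    "DesignConfig",
    "StudyDesign",
    "EffectSpec",
    "SyntheticTruth",
    "generate_design",
    "simulate_intensities",
    "render_peak_lists",
    "simulate_study",
]

CYCLE_STATES = ("follicular", "peri-ovulatory", "luteal")

# distinct sub-streams per operation so stages regenerate independently
_STREAMS = {"design": 11, "intensities": 23, "render": 37}


def _rng(seed: int, op: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[op]])


@dataclass
class DesignConfig:
    """Study-design knobs; defaults reproduce the reference study layout.

    12 females sampled over 27 cycles in total (three females for one cycle,
    three for two, six for three), per-phase quotas 56/104/52 animal samples,
    9 handling blanks and 22 room-air blanks.
    """

    n_females: int = 12
    cycles_per_female: tuple[int, ...] = (1, 1, 1, 2, 2, 2, 3, 3, 3, 3, 3, 3)
    state_quotas: dict[str, int] = field(
        default_factory=lambda: {"follicular": 56, "peri-ovulatory": 104, "luteal": 52}
    )
    n_handling_blanks: int = 9
    n_air_blanks: int = 22
    age_range: tuple[int, int] = (1, 11)
    n_parous: int = 5
    n_rooms: int = 3
    n_assistants: int = 4
    p_assistant: float = 0.3  # independent presence per assistant
    p_ultrasound_after: float = 0.8


@dataclass
class StudyDesign:
    """Females table + per-sample metadata table, fully reproducible from seed."""

    females: pd.DataFrame
    samples: pd.DataFrame
    config: DesignConfig
    seed: int

    @property
    def animal_samples(self) -> pd.DataFrame:
        return self.samples[~self.samples["is_blank"]]

    @property
    def blanks(self) -> pd.DataFrame:
        return self.samples[self.samples["is_blank"]]

    @property
    def batches(self) -> list[str]:
        return sorted(self.animal_samples["batch"].unique())


def generate_design(config: DesignConfig | None = None, seed: int = 0) -> StudyDesign:
    """Draw a complete sample-metadata table for the configured study.

    Cycle-state quotas are met exactly; every (female, cycle) batch receives
    at least one sample.  Raises ``ValueError`` when the quotas cannot be
    spread over the requested females/cycles.
    """
    config = config or DesignConfig()
    rng = _rng(seed, "design")

    if config.n_females < 1:
        raise ValueError("need at least one female")
    cpf = config.cycles_per_female
    if isinstance(cpf, int):
        cpf = (cpf,) * config.n_females
    if len(cpf) != config.n_females:
        raise ValueError("cycles_per_female length must equal n_females")
    if any(c < 1 for c in cpf):
        raise ValueError("each female needs at least one cycle")
    quotas = {s: int(config.state_quotas.get(s, 0)) for s in CYCLE_STATES}
    if any(q < 0 for q in quotas.values()):
        raise ValueError("cycle-state quotas must be nonnegative")
    total = sum(quotas.values())
    batches = [(f, c) for f in range(config.n_females) for c in range(cpf[f])]
    if total < len(batches):
        raise ValueError(
            f"quota infeasible: {total} animal samples cannot cover "
            f"{len(batches)} (female, cycle) batches with one sample each"
        )

    # females: ages from the observed discrete range, parity independent of age
    lo, hi = config.age_range
    ages = rng.integers(lo, hi + 1, size=config.n_females)
    parous_idx = set(rng.choice(config.n_females, size=config.n_parous, replace=False))
    rooms = rng.integers(1, config.n_rooms + 1, size=config.n_females)
    females = pd.DataFrame(
        {
            "female": [f"F{i + 1:02d}" for i in range(config.n_females)],
            "age": ages,
            "parity": ["parous" if i in parous_idx else "nulliparous" for i in range(config.n_females)],
            "room": [f"room{r}" for r in rooms],
        }
    )

    # distribute each state's quota over batches: even base + random remainder,
    # then guarantee every batch is non-empty by moving singles from the richest
    counts = {s: np.zeros(len(batches), dtype=int) for s in CYCLE_STATES}
    for s in CYCLE_STATES:
        q = quotas[s]
        base, rem = divmod(q, len(batches))
        counts[s][:] = base
        if rem:
            counts[s][rng.choice(len(batches), size=rem, replace=False)] += 1
    per_batch = sum(counts.values())
    while (per_batch == 0).any():
        empty = int(np.argmin(per_batch))
        donor = int(np.argmax(per_batch))
        s = max(CYCLE_STATES, key=lambda st: counts[st][donor])
        counts[s][donor] -= 1
        counts[s][empty] += 1
        per_batch = sum(counts.values())

    rows = []
    sid = 0
    for bi, (f, c) in enumerate(batches):
        frow = females.iloc[f]
        for s in CYCLE_STATES:
            for _ in range(int(counts[s][bi])):
                sid += 1
                # independent presence per assistant keeps the four flags
                # jointly estimable alongside the intercept
                present = rng.random(config.n_assistants) < config.p_assistant
                rows.append(
                    {
                        "sample_id": f"S{sid:04d}",
                        "female": frow["female"],
                        "age": int(frow["age"]),
                        "parity": frow["parity"],
                        "room": frow["room"],
                        "cycle": c + 1,
                        "batch": f"{frow['female']}-c{c + 1}",
                        "cycle_state": s,
                        "side": str(rng.choice(["left", "right"])),
                        "ultrasound": "after" if rng.random() < config.p_ultrasound_after else "before",
                        **{
                            f"a{j + 1}": ("yes" if present[j] else "no")
                            for j in range(config.n_assistants)
                        },
                        "is_blank": False,
                        "blank_type": "",
                    }
                )
    for k in range(config.n_handling_blanks + config.n_air_blanks):
        rows.append(
            {
                "sample_id": f"B{k + 1:03d}",
                "female": "",
                "age": np.nan,
                "parity": "",
                "room": f"room{rng.integers(1, config.n_rooms + 1)}",
                "cycle": 0,
                "batch": "blank",
                "cycle_state": "",
                "side": "",
                "ultrasound": "",
                **{f"a{j + 1}": "no" for j in range(config.n_assistants)},
                "is_blank": True,
                "blank_type": "handling" if k < config.n_handling_blanks else "room_air",
            }
        )
    samples = pd.DataFrame(rows)
    for s in CYCLE_STATES:  # exact quota check (construction guarantees it)
        assert (samples["cycle_state"] == s).sum() == quotas[s]
    return StudyDesign(females=females, samples=samples, config=config, seed=seed)


@dataclass
class EffectSpec:
    """Per-substance generative parameters.

    ``substances`` has one row per substance (animal substances then
    contaminants) with columns: id, rt (minutes), baseline (log-area),
    is_contaminant, inconsistent, cycle_<state> deviations (mean 0 over
    states), age_slope (per z-scored year), parity_shift (applied to parous
    females).  ``mz`` maps substance id -> tuple of (m/z, fraction) fragment
    compositions.  SDs are on the log scale.
    """

    substances: pd.DataFrame
    mz: dict[str, tuple[tuple[int, float], ...]]
    sigma_id: float = 0.5
    sigma_batch: float = 0.3
    sigma_resid: float = 0.5
    side_shift: float = 0.0
    ultrasound_shift: float = 0.0
    assistant_shifts: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)
    blank_carryover: float = 0.01
    # tube-borne contaminants are undiluted in blanks (no competing animal
    # signal on the adsorbent), so their blank level sits above animal level
    contaminant_blank_boost: float = 0.7

    def __post_init__(self) -> None:
        if min(self.sigma_id, self.sigma_batch, self.sigma_resid) < 0:
            raise ValueError("random-effect SDs must be nonnegative")
        contam = self.substances["is_contaminant"]
        eff = (
            self.substances[[c for c in self.substances.columns if c.startswith("cycle_")]]
            .abs()
            .sum(axis=1)
            + self.substances["age_slope"].abs()
            + self.substances["parity_shift"].abs()
        )
        if (contam & (eff > 0)).any():
            raise ValueError("contaminant substances must carry no planted effects")

    @property
    def substance_ids(self) -> list[str]:
        return list(self.substances.loc[~self.substances["is_contaminant"], "id"])

    @property
    def contaminant_ids(self) -> list[str]:
        return list(self.substances.loc[self.substances["is_contaminant"], "id"])

    @property
    def all_ids(self) -> list[str]:
        return list(self.substances["id"])

    @property
    def cycle_affected(self) -> set[str]:
        cols = [f"cycle_{s}" for s in CYCLE_STATES]
        mask = self.substances[cols].abs().sum(axis=1) > 0
        return set(self.substances.loc[mask, "id"])

    @property
    def age_affected(self) -> set[str]:
        return set(self.substances.loc[self.substances["age_slope"].abs() > 0, "id"])

    @property
    def parity_affected(self) -> set[str]:
        return set(self.substances.loc[self.substances["parity_shift"].abs() > 0, "id"])

    @property
    def inconsistent_ids(self) -> set[str]:
        return set(self.substances.loc[self.substances["inconsistent"], "id"])

    def contaminant_table(self, window: float = 0.05) -> list[ContaminantEntry]:
        """Known-contaminant list (RT window + characteristic m/z) for the filter."""
        out = []
        for r in self.substances[self.substances["is_contaminant"]].itertuples(index=False):
            mzs = frozenset(m for m, _ in self.mz[r.id])
            out.append(ContaminantEntry(r.rt - window, r.rt + window, mzs))
        return out

    @classmethod
    def random(
        cls,
        n_substances: int = 160,
        n_contaminants: int = 10,
        n_cycle: int = 6,
        n_age: int = 11,
        n_parity: int = 7,
        n_inconsistent: int = 0,
        effect_size: float = 1.0,
        baseline_mean: float = 11.5,
        baseline_sd: float = 1.0,
        rt_span: tuple[float, float] = (2.4, 46.6),
        n_fragments: int = 5,
        sigma_id: float = 0.5,
        sigma_batch: float = 0.3,
        sigma_resid: float = 0.5,
        seed: int = 0,
    ) -> "EffectSpec":
        """Draw a spec with planted cycle/age/parity substances.

        Effect-carrying substances are disjoint from contaminants (enforced);
        age slopes are mostly negative and parity shifts mostly favour
        nulliparous females, matching the direction structure expected of
        real profiles.  Default planted counts (6 cycle / 11 age / 7 parity)
        mirror the study's most-affected-substance counts.
        """
        rng = np.random.default_rng([int(seed), 53])
        n_total = n_substances + n_contaminants
        if n_cycle + n_age + n_parity + n_inconsistent > n_substances:
            raise ValueError("more planted substances than available")

        # well-separated RTs: even grid + small perturbation, shuffled assignment
        lo, hi = rt_span
        grid = np.linspace(lo, hi, n_total)
        step = (hi - lo) / max(n_total - 1, 1)
        rts = grid + rng.uniform(-0.2, 0.2, n_total) * min(step / 3, 0.05)
        ids = [f"sub{i + 1:03d}" for i in range(n_substances)] + [
            f"con{i + 1:02d}" for i in range(n_contaminants)
        ]
        order = rng.permutation(n_total)
        rt_assign = dict(zip([ids[i] for i in order], np.sort(rts)))

        base = rng.normal(baseline_mean, baseline_sd, n_total)
        cyc = np.zeros((n_total, 3))
        age = np.zeros(n_total)
        par = np.zeros(n_total)
        pick = rng.choice(n_substances, size=n_cycle + n_age + n_parity, replace=False)
        i_cyc, i_age, i_par = (
            pick[:n_cycle],
            pick[n_cycle : n_cycle + n_age],
            pick[n_cycle + n_age :],
        )
        # cycle: deviation profile peaking in one state (mostly luteal), mean 0
        peak_states = rng.choice([2, 2, 2, 2, 1, 1], size=n_cycle)
        for j, s_peak in zip(i_cyc, peak_states):
            v = np.full(3, -effect_size / 2)
            v[s_peak] = effect_size
            cyc[j] = v - v.mean()
        # age: majority decreasing with age
        signs_a = rng.permutation([-1] * max(1, int(round(n_age * 0.73))) + [1] * (n_age - max(1, int(round(n_age * 0.73)))))
        age[i_age] = signs_a * effect_size
        # parity: mostly higher in nulliparous (negative shift for parous)
        signs_p = rng.permutation([-1] * max(1, int(round(n_parity * 0.8))) + [1] * (n_parity - max(1, int(round(n_parity * 0.8)))))
        par[i_par] = signs_p * effect_size

        inconsistent = np.zeros(n_total, dtype=bool)
        if n_inconsistent:
            free = sorted(set(range(n_substances)) - set(pick))
            chosen = rng.choice(free, size=n_inconsistent, replace=False)
            inconsistent[chosen] = True

        df = pd.DataFrame(
            {
                "id": ids,
                "rt": [rt_assign[i] for i in ids],
                "baseline": base,
                "is_contaminant": [i >= n_substances for i in range(n_total)],
                "inconsistent": inconsistent,
                "cycle_follicular": cyc[:, 0],
                "cycle_peri-ovulatory": cyc[:, 1],
                "cycle_luteal": cyc[:, 2],
                "age_slope": age,
                "parity_shift": par,
            }
        )
        mz: dict[str, tuple[tuple[int, float], ...]] = {}
        for i, sid in enumerate(ids):
            frags = rng.choice(np.arange(30, 301), size=n_fragments, replace=False)
            w = np.sort(rng.dirichlet(np.ones(n_fragments)))[::-1]
            mz[sid] = tuple((int(m), float(f)) for m, f in zip(frags, w))
        return cls(
            substances=df,
            mz=mz,
            sigma_id=sigma_id,
            sigma_batch=sigma_batch,
            sigma_resid=sigma_resid,
        )


@dataclass
class SyntheticTruth:
    """Everything needed to score a downstream analysis against the generator."""

    latent: pd.DataFrame  # samples x substances, raw areas
    cycle_affected: set[str]
    age_affected: set[str]
    parity_affected: set[str]
    contaminants: set[str]
    female_effects: dict[str, float]
    batch_effects: dict[str, float]
    seed: int

    def to_json(self, path: str | Path) -> None:
        obj = {
            "cycle_affected": sorted(self.cycle_affected),
            "age_affected": sorted(self.age_affected),
            "parity_affected": sorted(self.parity_affected),
            "contaminants": sorted(self.contaminants),
            "female_effects": self.female_effects,
            "batch_effects": self.batch_effects,
            "seed": self.seed,
            "latent": {
                "index": list(self.latent.index),
                "columns": list(self.latent.columns),
                "values": self.latent.to_numpy().tolist(),
            },
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        obj = json.loads(Path(path).read_text())
        lat = pd.DataFrame(
            obj["latent"]["values"], index=obj["latent"]["index"], columns=obj["latent"]["columns"]
        )
        lat.index.name = "sample_id"
        return cls(
            latent=lat,
            cycle_affected=set(obj["cycle_affected"]),
            age_affected=set(obj["age_affected"]),
            parity_affected=set(obj["parity_affected"]),
            contaminants=set(obj["contaminants"]),
            female_effects=obj["female_effects"],
            batch_effects=obj["batch_effects"],
            seed=obj["seed"],
        )


def zscore_ages(females: pd.DataFrame) -> pd.Series:
    """z-transform female ages (sample SD, ddof=1) keyed by female id."""
    ages = females.set_index("female")["age"].astype(float)
    sd = ages.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return ages * 0.0
    return (ages - ages.mean()) / sd


def simulate_intensities(
    design: StudyDesign, spec: EffectSpec, seed: int = 0
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw the latent area matrix (samples x substances).

    Animal samples follow
    ``log-area = b_s + c_s[state] + a_s*z(age) + p_s*[parous] + nuisance
    + u_female + u_batch + eps``; blanks carry contaminants at full intensity
    plus a small carryover fraction of animal substances.
    """
    rng = _rng(seed, "intensities")
    subs = spec.substances.set_index("id")
    ids = spec.all_ids
    n_sub = len(ids)
    samples = design.samples
    zage = zscore_ages(design.females)

    u_f = dict(zip(design.females["female"], rng.normal(0, spec.sigma_id, len(design.females))))
    batch_ids = design.batches
    u_b = dict(zip(batch_ids, rng.normal(0, spec.sigma_batch, len(batch_ids))))
    eps = rng.normal(0, spec.sigma_resid, (len(samples), n_sub))

    base = subs.loc[ids, "baseline"].to_numpy()
    contam = subs.loc[ids, "is_contaminant"].to_numpy()
    cyc = {
        s: subs.loc[ids, f"cycle_{s}"].to_numpy() for s in CYCLE_STATES
    }
    a_slope = subs.loc[ids, "age_slope"].to_numpy()
    p_shift = subs.loc[ids, "parity_shift"].to_numpy()

    log_area = np.empty((len(samples), n_sub))
    for i, row in enumerate(samples.itertuples(index=False)):
        if row.is_blank:
            la = base.copy()
            la[~contam] += np.log(spec.blank_carryover) if spec.blank_carryover > 0 else -np.inf
            la[contam] += spec.contaminant_blank_boost
        else:
            la = (
                base
                + cyc[row.cycle_state]
                + a_slope * zage[row.female]
                + p_shift * (row.parity == "parous")
                + spec.side_shift * (row.side == "right")
                + spec.ultrasound_shift * (row.ultrasound == "after")
                + u_f[row.female]
                + u_b[row.batch]
            )
            for j, flag in enumerate((row.a1, row.a2, row.a3, row.a4)):
                if flag == "yes" and j < len(spec.assistant_shifts):
                    la = la + spec.assistant_shifts[j]
            # contaminants are tube-derived: no animal-linked terms
            la[contam] = base[contam]
        log_area[i] = la + eps[i]
    areas = pd.DataFrame(np.exp(log_area), index=samples["sample_id"], columns=ids)
    truth = SyntheticTruth(
        latent=areas,
        cycle_affected=spec.cycle_affected,
        age_affected=spec.age_affected,
        parity_affected=spec.parity_affected,
        contaminants=set(spec.contaminant_ids),
        female_effects={k: float(v) for k, v in u_f.items()},
        batch_effects={k: float(v) for k, v in u_b.items()},
        seed=seed,
    )
    return areas, truth


def render_peak_lists(
    areas: pd.DataFrame,
    spec: EffectSpec,
    jitter_sd: float = 0.005,
    dropout_rate: float = 0.0,
    seed: int = 0,
    batch_rt_shifts: dict[str, float] | None = None,
    batch_map: dict[str, str] | None = None,
) -> dict[str, PeakList]:
    """Render one peak list per sample from the latent area matrix.

    Each positive-area substance becomes one peak at its true RT plus
    Gaussian jitter (plus an optional per-batch RT offset); peaks drop out
    independently with ``dropout_rate``.  Substances flagged ``inconsistent``
    get a freshly drawn fragment set per peak, so their grouped spectra fail
    the downstream consistency check.
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be nonnegative")
    if not 0 <= dropout_rate < 1:
        raise ValueError("dropout_rate must be in [0, 1)")
    rng = _rng(seed, "render")
    rts = spec.substances.set_index("id")["rt"]
    inconsistent = spec.inconsistent_ids
    out: dict[str, PeakList] = {}
    for sid, row in areas.iterrows():
        shift = 0.0
        if batch_rt_shifts and batch_map:
            shift = batch_rt_shifts.get(batch_map.get(sid, ""), 0.0)
        peaks = []
        for sub, area in row.items():
            if area <= 0:
                continue
            if dropout_rate and rng.random() < dropout_rate:
                continue
            rt = rts[sub] + shift + (rng.normal(0, jitter_sd) if jitter_sd else 0.0)
            if sub in inconsistent:
                frags = rng.choice(np.arange(30, 301), size=len(spec.mz[sub]), replace=False)
                fracs = [f for _, f in spec.mz[sub]]
                spectrum = {int(m): float(area) * f for m, f in zip(frags, fracs)}
            else:
                spectrum = {m: float(area) * f for m, f in spec.mz[sub]}
            peaks.append(Peak(str(sid), float(max(rt, 1e-6)), float(area), spectrum))
        out[str(sid)] = PeakList(str(sid), peaks)
    return out


def simulate_study(
    config: DesignConfig | None = None,
    spec: EffectSpec | None = None,
    seed: int = 0,
    jitter_sd: float = 0.005,
    dropout_rate: float = 0.0,
    batch_rt_shifts: dict[str, float] | None = None,
) -> tuple[StudyDesign, dict[str, PeakList], SyntheticTruth]:
    """Convenience: design -> latent intensities -> rendered peak lists."""
    design = generate_design(config, seed)
    spec = spec or EffectSpec.random(seed=seed)
    areas, truth = simulate_intensities(design, spec, seed)
    batch_map = dict(zip(design.samples["sample_id"], design.samples["batch"]))
    peaklists = render_peak_lists(
        areas,
        spec,
        jitter_sd=jitter_sd,
        dropout_rate=dropout_rate,
        seed=seed,
        batch_rt_shifts=batch_rt_shifts,
        batch_map=batch_map,
    )
    return design, peaklists, truth
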