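"""Synthetic methylation data with planted co-methylation structure.

The generator works on the M-value (logit2) scale, where Gaussian latent
factors are natural, and maps deterministically to bounded beta values:

    M_p(s) = mu_p + lambda * z_m(s) + gamma * u_d(s)
             + delta * 1[s is case and d affected] + eps,
    beta   = 2^M / (2^M + 1)

with one standard-normal module factor z_m per latent co-methylation module
m, one DMR factor u_d per region d (driving within-region probe
correlation), probe-level offsets mu_p ~ N(0, 1) fixed per probe, and
independent noise eps ~ N(0, sigma^2).  Case samples of affected DMRs are
shifted by delta on the M scale, emulating group-wise methylation
differences.

Each logical source of randomness (layout, mu, z, u, eps, missingness)
draws from its own named stream derived from one global seed, so e.g.
changing the missing rate never perturbs the signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import DMR, DMRSet, MethylationMatrix, SampleTable, ValidationError

_STREAMS = ("layout", "mu", "z", "u", "eps", "missing")


@dataclass
class SimulationConfig:
    """Generative-model parameters.

    module_loading (lambda) scales the shared cross-DMR factor, so raising
    it strengthens between-region co-methylation within a module;
    within_dmr_loading (gamma) sets how tightly a region's own probes move
    together; noise_sd (sigma) is the independent probe noise, all on the
    M-value scale.  group_effect (delta) shifts affected DMRs in case
    samples by that many M-value units.
    """

    n_samples: int = 60
    n_dmrs: int = 40
    probes_per_dmr: tuple[int, int] = (2, 10)
    n_modules: int = 4
    module_assignment: dict[int, int] | None = None  # DMR index -> module (0 = background)
    module_loading: float = 1.0
    within_dmr_loading: float = 0.5
    noise_sd: float = 0.5
    group_effect: float = 2.0
    case_fraction: float = 0.5
    missing_rate: float = 0.0
    affected_dmrs: list[int] | None = None  # DMR indices; default: all of module 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_dmrs <= 0:
            raise ValidationError("n_samples and n_dmrs must be positive")
        if self.n_modules < 0:
            raise ValidationError("n_modules must be non-negative")
        if self.n_modules > self.n_dmrs:
            raise ValidationError("n_modules cannot exceed n_dmrs")
        lo, hi = self.probes_per_dmr
        if lo < 1 or hi < lo:
            raise ValidationError("probes_per_dmr must be a range with 1 <= lo <= hi")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValidationError("case_fraction must lie in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if self.module_loading < 0 or self.within_dmr_loading < 0:
            raise ValidationError("loadings must be non-negative")


@dataclass
class GroundTruth:
    """What the generator planted: module membership and affected regions."""

    module_assignment: dict[str, int]  # dmr_id -> module id (0 = background)
    affected_dmrs: list[str]
    probe_mu: dict[str, float] = field(default_factory=dict)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(s) for name, s in zip(_STREAMS, children)}


def _default_modules(n_dmrs: int, n_modules: int) -> dict[int, int]:
    """Contiguous, near-even split of DMRs over modules; none left background."""
    if n_modules == 0:
        return {i: 0 for i in range(n_dmrs)}
    bounds = np.linspace(0, n_dmrs, n_modules + 1).astype(int)
    out = {}
    for m in range(n_modules):
        for i in range(bounds[m], bounds[m + 1]):
            out[i] = m + 1
    return out


def m_to_beta(m: np.ndarray) -> np.ndarray:
    """Logistic (base 2) map from M-values to beta values in (0, 1)."""
    return 1.0 / (1.0 + np.exp2(-m))


def simulate(
    config: SimulationConfig,
) -> tuple[MethylationMatrix, DMRSet, SampleTable, GroundTruth]:
    """Draw one dataset; identical config (incl. seed) gives identical output."""
    rng = _streams(config.seed)
    n_s, n_d = config.n_samples, config.n_dmrs

    modules = (
        dict(config.module_assignment)
        if config.module_assignment is not None
        else _default_modules(n_d, config.n_modules)
    )
    mods_present = sorted({m for m in modules.values() if m > 0})
    if mods_present and mods_present != list(range(1, max(mods_present) + 1)):
        raise ValidationError("module ids must be dense 1..n_modules")

    lo, hi = config.probes_per_dmr
    probes_per = rng["layout"].integers(lo, hi + 1, size=n_d)

    dmr_ids = [f"DMR{i + 1:04d}" for i in range(n_d)]
    dmrs, probe_ids, probe_dmr_idx = [], [], []
    cursor = 0
    for i in range(n_d):
        members = [f"cg{cursor + j + 1:08d}" for j in range(probes_per[i])]
        cursor += probes_per[i]
        start = 10_000 * (i + 1)
        dmrs.append(
            DMR(
                dmr_ids[i],
                f"chr{i % 22 + 1}",
                start,
                start + 500 * len(members),
                f"GENE{i + 1:04d}",
                members,
            )
        )
        probe_ids.extend(members)
        probe_dmr_idx.extend([i] * probes_per[i])
    n_p = len(probe_ids)
    probe_dmr_idx = np.asarray(probe_dmr_idx)

    if config.affected_dmrs is not None:
        affected = set(config.affected_dmrs)
    else:
        affected = {i for i in range(n_d) if modules[i] == 1}
    bad = [i for i in affected if not 0 <= i < n_d]
    if bad:
        raise ValidationError(f"affected DMR indices out of range: {bad}")

    n_case = int(round(n_s * config.case_fraction))
    n_case = min(max(n_case, 1), n_s - 1)
    is_case = np.zeros(n_s, dtype=bool)
    is_case[:n_case] = True

    mu = rng["mu"].standard_normal(n_p)
    n_mod = max([0, *modules.values()])
    z = rng["z"].standard_normal((n_mod, n_s)) if n_mod else np.zeros((0, n_s))
    u = rng["u"].standard_normal((n_d, n_s))
    eps = rng["eps"].standard_normal((n_p, n_s)) * config.noise_sd

    mod_of_probe = np.array([modules[i] for i in probe_dmr_idx])
    m_vals = mu[:, None] + eps
    has_mod = mod_of_probe > 0
    if n_mod:
        m_vals[has_mod] += config.module_loading * z[mod_of_probe[has_mod] - 1]
    m_vals += config.within_dmr_loading * u[probe_dmr_idx]
    affected_probe = np.isin(probe_dmr_idx, list(affected))
    m_vals[np.ix_(affected_probe, is_case)] += config.group_effect

    beta = m_to_beta(m_vals)
    if config.missing_rate > 0:
        drop = rng["missing"].random((n_p, n_s)) < config.missing_rate
        beta = np.where(drop, np.nan, beta)

    sample_ids = [f"S{j + 1:04d}" for j in range(n_s)]
    groups = ["case" if c else "control" for c in is_case]
    matrix = MethylationMatrix(probe_ids, sample_ids, beta)
    table = SampleTable(sample_ids, groups)
    truth = GroundTruth(
        module_assignment={dmr_ids[i]: modules[i] for i in range(n_d)},
        affected_dmrs=sorted(dmr_ids[i] for i in affected),
        probe_mu=dict(zip(probe_ids, mu)),
    )
    return matrix, DMRSet(dmrs), table, truth


FIXTURES: dict[str, SimulationConfig] = {
    # 6 DMRs / 2 modules / 12 probes / 20 samples: smallest end-to-end case
    "tiny": SimulationConfig(
        n_samples=20, n_dmrs=6, probes_per_dmr=(2, 2), n_modules=2, seed=11
    ),
    # 40 DMRs / 4 modules / ~160 probes / 60 samples: module-recovery benchmark
    "blocks": SimulationConfig(
        n_samples=60, n_dmrs=40, probes_per_dmr=(3, 5), n_modules=4, seed=7
    ),
    # the real problem size: 610 DMRs, ~3683 CpGs, 60 samples; two latent
    # networks of 30 and 25 regions among a mostly-background DMR list
    "paper_shape": SimulationConfig(
        n_samples=60,
        n_dmrs=610,
        probes_per_dmr=(2, 10),
        n_modules=2,
        module_assignment={
            i: (1 if i < 30 else 2 if i < 55 else 0) for i in range(610)
        },
        seed=59,
    ),
}


def make_fixture(name: str):
    """Named, fixed-seed datasets used throughout the tests and docs."""
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    return simulate(FIXTURES[name])
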