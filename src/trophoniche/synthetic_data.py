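"""Synthetic tracer data with the statistical structure the analysis assumes.

Three generators cover the pipeline's inputs:

* ``generate_prey_samples`` — per-(species, region) bivariate-normal isotope
  draws at configurable means/SDs (tracers independent within a source unless
  a covariance is supplied; the reference prey table prints none).
* ``generate_consumers`` — forward model of the mixing equation: a consumer
  with true diet p gets per-tracer values drawn from
  Normal(Σ p_k(μ_k+λ), Σ p_k²(σ_k²+τ²) + process² + analytical²).
* ``generate_fa_profiles`` — compositional fatty-acid profiles as Dirichlet
  draws scaled to mass percent, with species-specific concentration vectors
  chosen so species are separable by permutation tests downstream.

The shipped ``regime_shift`` scenario is parameterised from the reference
prey table for the St. Lawrence system (seven species over two regions,
pooled into six functional groups) and plants a two-period diet-group
structure — specialist-leaning groups before the regime boundary, a krill
"specialist-generalist" group plus a true-generalist group after — so the
full pipeline can be exercised at desk scale without any download.  It is
illustrative of the study system, not ground truth for it.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mixing_model import TDFSpec

__all__ = [
    "ScenarioError",
    "SourceSpec",
    "GroupSpec",
    "Scenario",
    "generate_prey_samples",
    "generate_consumers",
    "generate_fa_profiles",
    "pool_specs",
    "table1_species_specs",
    "functional_group_specs",
    "default_fa_alphas",
    "regime_shift_scenario",
    "scenario_to_dict",
    "scenario_from_dict",
    "FUNCTIONAL_GROUP_MAP",
]


class ScenarioError(ValueError):
    """Invalid synthetic-data specification."""


@dataclass(frozen=True)
class SourceSpec:
    """One prey source's tracer distribution (and optional FA concentration).

    ``mu_c``/``sd_c`` and ``mu_n``/``sd_n`` are the δ13C and δ15N mean/SD in
    ‰; ``n`` the sample count to draw.  ``cov_cn`` is an optional δ13C–δ15N
    covariance (defaults to 0: tracers independent).  ``fa_alpha`` is a
    Dirichlet concentration vector for compositional FA simulation.
    ``ecology`` is a guild tag consulted by the prey-merging rules.
    """

    name: str
    mu_c: float
    sd_c: float
    mu_n: float
    sd_n: float
    n: int
    region: str = "NA"
    cov_cn: float = 0.0
    cn_mean: float | None = None
    cn_sd: float = 0.0
    lipid_mean: float | None = None
    lipid_sd: float = 0.0
    fa_alpha: tuple[float, ...] | None = None
    n_fa: int | None = None
    ecology: str = ""

    def __post_init__(self) -> None:
        if self.sd_c < 0 or self.sd_n < 0:
            raise ScenarioError(f"source {self.name!r}: SDs must be non-negative")
        if self.n < 1:
            raise ScenarioError(f"source {self.name!r}: n must be >= 1")
        if self.fa_alpha is not None and min(self.fa_alpha) <= 0:
            raise ScenarioError(f"source {self.name!r}: fa_alpha entries must be > 0")
        cov_max = self.sd_c * self.sd_n
        if abs(self.cov_cn) > cov_max + 1e-12:
            raise ScenarioError(f"source {self.name!r}: |cov_cn| exceeds sd_c*sd_n")

    @property
    def unit(self) -> str:
        """Unique (species, region) label."""
        return self.name if self.region == "NA" else f"{self.name}_{self.region.lower()}"


@dataclass(frozen=True)
class GroupSpec:
    """A planted consumer diet group: label, period, true diet, group size."""

    label: str
    period: str
    diet: tuple[float, ...]
    n: int

    def __post_init__(self) -> None:
        d = np.asarray(self.diet, float)
        if d.min() < 0 or abs(d.sum() - 1.0) > 1e-12:
            raise ScenarioError(f"group {self.label!r}: diet must lie on the simplex")
        if self.n < 1:
            raise ScenarioError(f"group {self.label!r}: n must be >= 1")


@dataclass(frozen=True)
class Scenario:
    """Full synthetic study design.

    ``sources`` are the mixing sources consumers are generated from (their
    order defines the diet-vector order).  ``prey_specs`` optionally carries a
    finer (e.g. species-level) prey table specification; it defaults to
    ``sources``.  ``process_sd_extra`` is additional per-tracer process noise
    (‰) beyond source/TDF variability, and ``analytical_sd`` the instrument
    noise (defaults 0.11/0.12‰).
    """

    sources: tuple[SourceSpec, ...]
    groups: tuple[GroupSpec, ...]
    tdf: TDFSpec = TDFSpec()
    process_sd_extra: tuple[float, float] = (0.2, 0.2)
    analytical_sd: tuple[float, float] = (0.11, 0.12)
    period_windows: dict = field(
        default_factory=lambda: {
            "pre": (dt.date(1998, 6, 1), dt.date(2001, 11, 30)),
            "post": (dt.date(2002, 6, 1), dt.date(2006, 11, 30)),
        }
    )
    prey_specs: tuple[SourceSpec, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sources:
            raise ScenarioError("scenario needs at least one source")
        k = len(self.sources)
        for grp in self.groups:
            if len(grp.diet) != k:
                raise ScenarioError(
                    f"group {grp.label!r}: diet length {len(grp.diet)} != {k} sources"
                )
            if grp.period not in self.period_windows:
                raise ScenarioError(f"group {grp.label!r}: unknown period {grp.period!r}")

    @property
    def source_names(self) -> list[str]:
        return [s.unit for s in self.sources]

    def with_seed(self, seed: int) -> "Scenario":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def generate_prey_samples(specs: list[SourceSpec], seed: int | None = None) -> pd.DataFrame:
    """Draw per-source isotope samples.

    Returns a table with columns species, region, year, d13C, d15N, cn_ratio,
    pct_lipid; ``n`` rows per spec, tracers drawn from the spec's
    (bivariate) normal.  Deterministic given identical specs and seed.
    """
    if not specs:
        raise ScenarioError("specs must be non-empty")
    rng = np.random.default_rng(seed)
    frames = []
    for spec in specs:
        cov = np.array(
            [[spec.sd_c**2, spec.cov_cn], [spec.cov_cn, spec.sd_n**2]], float
        )
        if spec.cov_cn == 0.0:
            d13c = rng.normal(spec.mu_c, spec.sd_c, size=spec.n)
            d15n = rng.normal(spec.mu_n, spec.sd_n, size=spec.n)
        else:
            draws = rng.multivariate_normal([spec.mu_c, spec.mu_n], cov, size=spec.n)
            d13c, d15n = draws[:, 0], draws[:, 1]
        frames.append(
            pd.DataFrame(
                {
                    "species": spec.name,
                    "region": spec.region,
                    "year": rng.integers(1999, 2006, size=spec.n),
                    "d13C": d13c,
                    "d15N": d15n,
                    "cn_ratio": (
                        rng.normal(spec.cn_mean, spec.cn_sd, size=spec.n)
                        if spec.cn_mean is not None
                        else np.nan
                    ),
                    "pct_lipid": (
                        rng.normal(spec.lipid_mean, spec.lipid_sd, size=spec.n)
                        if spec.lipid_mean is not None
                        else np.nan
                    ),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_consumers(scenario: Scenario) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Forward-simulate consumer tracer values from planted group diets.

    Returns ``(consumers, truth)``: consumers with columns id, date, period,
    group, d13C, d15N; truth in long format (id, source, proportion).
    Consumer values are exact mixture draws: per tracer i,
    Normal(Σ_k p_k(μ_ik+λ_i), Σ_k p_k²(σ_ik²+τ_i²) + process_i² + analytical_i²).
    """
    rng = np.random.default_rng(scenario.seed)
    mu = np.array([[s.mu_c, s.mu_n] for s in scenario.sources])  # (K, 2)
    sd = np.array([[s.sd_c, s.sd_n] for s in scenario.sources])
    lam = scenario.tdf.means
    tau = scenario.tdf.sds
    extra = np.asarray(scenario.process_sd_extra, float) ** 2
    anal = np.asarray(scenario.analytical_sd, float) ** 2

    rows, truth_rows = [], []
    counter = 0
    for grp in scenario.groups:
        p = np.asarray(grp.diet, float)
        mean = p @ (mu + lam)
        var = (p**2) @ (sd**2 + tau**2) + extra + anal
        start, end = scenario.period_windows[grp.period]
        years = list(range(start.year, end.year + 1))
        for _ in range(grp.n):
            counter += 1
            cid = f"FW{counter:03d}"
            year = int(rng.choice(years))
            # feeding-season date: uniform over June 1 – Nov 30
            day0 = dt.date(year, 6, 1).toordinal()
            day1 = dt.date(year, 11, 30).toordinal()
            date = dt.date.fromordinal(int(rng.integers(day0, day1 + 1)))
            vals = rng.normal(mean, np.sqrt(var))
            rows.append(
                {
                    "id": cid,
                    "date": date.isoformat(),
                    "period": grp.period,
                    "group": grp.label,
                    "d13C": vals[0],
                    "d15N": vals[1],
                }
            )
            for src, pk in zip(scenario.source_names, p):
                truth_rows.append({"id": cid, "source": src, "proportion": pk})
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def generate_fa_profiles(
    specs: list[SourceSpec],
    seed: int | None = None,
    fa_names: list[str] | None = None,
    no_noise: bool = False,
) -> pd.DataFrame:
    """Compositional FA profiles: one Dirichlet draw per individual, scaled to
    mass percent (rows sum to 100).

    Each spec must carry a ``fa_alpha`` of length ``len(fa_names)``; the draw
    count per spec is ``n_fa`` (defaulting to ``n``).  With ``no_noise`` the
    Dirichlet is replaced by its mean (a point mass), giving identical rows.
    """
    if fa_names is None:
        from .tracer_prep import extended_dietary_subset

        fa_names = list(extended_dietary_subset())
    for spec in specs:
        if spec.fa_alpha is None:
            raise ScenarioError(f"source {spec.name!r} lacks fa_alpha")
        if len(spec.fa_alpha) != len(fa_names):
            raise ScenarioError(
                f"source {spec.name!r}: fa_alpha length {len(spec.fa_alpha)} "
                f"!= {len(fa_names)} FA names"
            )
    rng = np.random.default_rng(seed)
    frames = []
    counter = 0
    for spec in specs:
        alpha = np.asarray(spec.fa_alpha, float)
        n = spec.n_fa if spec.n_fa is not None else spec.n
        if no_noise:
            comp = np.tile(alpha / alpha.sum(), (n, 1)) * 100.0
        else:
            comp = rng.dirichlet(alpha, size=n) * 100.0
        frame = pd.DataFrame(comp, columns=fa_names)
        frame.insert(0, "id", [f"{spec.unit}-{counter + i + 1:03d}" for i in range(n)])
        frame.insert(1, "species", spec.name)
        frame.insert(2, "region", spec.region)
        counter += n
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Reference parameterization (St. Lawrence prey table)
# ---------------------------------------------------------------------------

#: Species-level prey specs: seven species, Estuary (Est) and Gulf rows where
#: both regions were sampled. Values are the printed study means/SDs.
_TABLE1_ROWS = [
    # name, region, mu_c, sd_c, mu_n, sd_n, n, cn_mean, cn_sd, lipid_mean, lipid_sd, ecology
    ("sandlance", "Est", -18.7, 0.5, 10.8, 0.3, 21, 3.16, 0.05, 2.9, 1.7, "lean pelagic fish"),
    ("sandlance", "Gulf", -18.8, 0.5, 10.9, 0.4, 6, 3.17, 0.02, 3.7, 1.8, "lean pelagic fish"),
    ("copepods", "Est", -18.4, 0.9, 9.3, 0.4, 42, 3.25, 0.13, 16.5, 3.6, "grazing zooplankton"),
    ("herring", "Est", -17.9, 0.9, 12.7, 0.6, 40, 3.12, 0.06, 7.1, 3.5, "lipid-rich pelagic fish"),
    ("herring", "Gulf", -19.6, 0.3, 12.2, 0.5, 10, 3.22, 0.08, None, 0.0, "lipid-rich pelagic fish"),
    ("capelin", "Est", -18.7, 0.3, 12.4, 0.4, 100, 3.16, 0.03, 2.8, 3.0, "lipid-rich pelagic fish"),
    ("capelin", "Gulf", -19.5, 0.2, 12.1, 0.4, 10, 3.14, 0.04, None, 0.0, "lipid-rich pelagic fish"),
    ("northern_krill", "Est", -19.5, 0.5, 10.7, 0.4, 110, 3.20, 0.05, 3.2, 1.0, "omnivorous krill"),
    ("amphipods", "Est", -19.2, 0.4, 11.9, 0.4, 34, 3.38, 0.10, 4.2, 1.5, "carnivorous zooplankton"),
    ("arctic_krill", "Est", -18.7, 0.3, 9.3, 0.6, 28, 3.23, 0.08, 6.5, 0.8, "grazing zooplankton"),
]

#: The study's six functional groups over the species-level units.
FUNCTIONAL_GROUP_MAP: dict[str, list[str]] = {
    "arctic_krill_copepods": ["arctic_krill_est", "copepods_est"],
    "northern_krill": ["northern_krill_est"],
    "capelin_herring_est": ["capelin_est", "herring_est"],
    "capelin_herring_gulf": ["capelin_gulf", "herring_gulf"],
    "amphipods": ["amphipods_est"],
    "sandlance": ["sandlance_est", "sandlance_gulf"],
}


def table1_species_specs(fa_names: list[str] | None = None) -> list[SourceSpec]:
    """The ten (species, region) prey specs at the reference means/SDs,
    with default FA concentration vectors attached."""
    alphas = default_fa_alphas(fa_names)
    return [
        SourceSpec(
            name=name,
            region=region,
            mu_c=mu_c,
            sd_c=sd_c,
            mu_n=mu_n,
            sd_n=sd_n,
            n=n,
            cn_mean=cn,
            cn_sd=cn_sd,
            lipid_mean=lip,
            lipid_sd=lip_sd,
            fa_alpha=tuple(alphas[name]),
            ecology=eco,
        )
        for name, region, mu_c, sd_c, mu_n, sd_n, n, cn, cn_sd, lip, lip_sd, eco in _TABLE1_ROWS
    ]


def pool_specs(specs: list[SourceSpec], name: str, region: str = "NA") -> SourceSpec:
    """Pool several specs into one by exact moment pooling.

    Pooled mean is the sample-size weighted mean; pooled variance combines
    within- and between-spec components so it equals the variance of the
    concatenated samples the specs summarise.
    """
    if not specs:
        raise ScenarioError("cannot pool an empty spec list")
    n = sum(s.n for s in specs)

    def _pool(mus, sds):
        mu = sum(s.n * m for s, m in zip(specs, mus)) / n
        if n == len(specs):  # all singletons: no within-variance information
            return mu, 0.0
        ss = sum((s.n - 1) * sd**2 + s.n * (m - mu) ** 2 for s, m, sd in zip(specs, mus, sds))
        return mu, float(np.sqrt(ss / (n - 1)))

    mu_c, sd_c = _pool([s.mu_c for s in specs], [s.sd_c for s in specs])
    mu_n, sd_n = _pool([s.mu_n for s in specs], [s.sd_n for s in specs])
    eco = specs[0].ecology if len({s.ecology for s in specs}) == 1 else ""
    return SourceSpec(
        name=name, region=region, mu_c=mu_c, sd_c=sd_c, mu_n=mu_n, sd_n=sd_n, n=n, ecology=eco
    )


def functional_group_specs() -> list[SourceSpec]:
    """The six functional-group sources, pooled from the species-level table.

    Isotope moments are pooled exactly; the FA concentration vector is the
    sample-size-weighted average of the member species' vectors.
    """
    species = {s.unit: s for s in table1_species_specs()}
    out = []
    for group, units in FUNCTIONAL_GROUP_MAP.items():
        members = [species[u] for u in units]
        pooled = pool_specs(members, name=group)
        alpha = np.average(
            [m.fa_alpha for m in members], axis=0, weights=[m.n for m in members]
        )
        out.append(replace(pooled, fa_alpha=tuple(alpha)))
    return out


def default_fa_alphas(fa_names: list[str] | None = None) -> dict[str, np.ndarray]:
    """Species-specific Dirichlet concentrations over the extended dietary FAs.

    A shared baseline plus species-specific boosts on the FAs described as
    discriminating in forage-species work (long-chain monounsaturates and
    16:1n7 for copepods; 14:0 for capelin vs herring; 18:1n9/16:4n1 and the
    essential FAs for the krill species).  Total concentration ~250 gives
    within-species compositional scatter of a few percent, comparable to
    chromatographic replicates of real forage species.
    """
    if fa_names is None:
        from .tracer_prep import extended_dietary_subset

        fa_names = list(extended_dietary_subset())
    idx = {name: i for i, name in enumerate(fa_names)}
    base = np.full(len(fa_names), 2.0)
    for heavy in ("16:1n7", "18:1n9", "18:1n7", "20:5n3", "22:6n3", "14:0"):
        if heavy in idx:
            base[idx[heavy]] = 15.0

    def boosted(**boosts: float) -> np.ndarray:
        a = base.copy()
        for fa, mult in boosts.items():
            if fa in idx:
                a[idx[fa]] *= mult
        return a

    return {
        "copepods": boosted(**{"20:1n9": 12, "20:1n11": 10, "22:1n11": 12, "16:1n7": 2.5}),
        "capelin": boosted(**{"14:0": 2.5, "16:1n7": 1.8, "18:1n9": 1.5}),
        "herring": boosted(**{"20:1n9": 4, "22:1n11": 5, "18:1n9": 1.8}),
        "sandlance": boosted(**{"20:5n3": 1.8, "22:6n3": 2.2, "18:2n6": 3}),
        "northern_krill": boosted(**{"18:1n9": 2.2, "20:5n3": 2.0, "16:4n1": 6}),
        "arctic_krill": boosted(**{"16:4n1": 14, "20:5n3": 2.4, "18:4n3": 5}),
        "amphipods": boosted(**{"22:1n11": 7, "20:1n9": 6, "18:1n7": 2.5, "22:6n3": 1.6}),
    }


def regime_shift_scenario(seed: int = 0) -> Scenario:
    """The default two-period study design (illustrative, not ground truth).

    Six functional-group sources pooled from the reference prey table; five
    planted diet groups sized to a 99-consumer study: three pre-period groups
    (krill specialists, an intermediate "specialist-generalist" majority, and
    pelagic-fish specialists) and two post-period groups (a zooplankton
    specialist-generalist group and a true-generalist majority).

    The prey table is generated at the functional-group level (the groups the
    study fixed before mixing), so the data-driven aggregation stage recovers
    exactly these six sources; species-level specs remain available via
    :func:`table1_species_specs` for finer-grained analyses.
    """
    sources = tuple(functional_group_specs())
    # source order: arctic_krill_copepods, northern_krill, capelin_herring_est,
    #               capelin_herring_gulf, amphipods, sandlance
    groups = (
        GroupSpec("G1.1", "pre", (0.89, 0.02, 0.05, 0.02, 0.01, 0.01), 12),
        GroupSpec("G1.2", "pre", (0.45, 0.05, 0.40, 0.04, 0.03, 0.03), 27),
        GroupSpec("G1.3", "pre", (0.10, 0.04, 0.70, 0.08, 0.04, 0.04), 6),
        GroupSpec("G2.1", "post", (0.55, 0.30, 0.02, 0.02, 0.09, 0.02), 22),
        GroupSpec("G2.2", "post", (0.20, 0.15, 0.22, 0.18, 0.10, 0.15), 32),
    )
    return Scenario(sources=sources, groups=groups, tdf=TDFSpec(), seed=seed)


# ---------------------------------------------------------------------------
# Config-file round trip
# ---------------------------------------------------------------------------

def scenario_to_dict(scenario: Scenario) -> dict:
    """Plain-dict form of a scenario (YAML/JSON-serialisable)."""

    def spec_d(s: SourceSpec) -> dict:
        d = {
            "name": s.name,
            "region": s.region,
            "mu_c": s.mu_c,
            "sd_c": s.sd_c,
            "mu_n": s.mu_n,
            "sd_n": s.sd_n,
            "n": s.n,
        }
        for opt in ("cov_cn", "cn_mean", "cn_sd", "lipid_mean", "lipid_sd", "n_fa", "ecology"):
            val = getattr(s, opt)
            if val not in (None, 0.0, ""):
                d[opt] = val
        if s.fa_alpha is not None:
            d["fa_alpha"] = list(s.fa_alpha)
        return d

    return {
        "sources": [spec_d(s) for s in scenario.sources],
        "prey_specs": (
            [spec_d(s) for s in scenario.prey_specs] if scenario.prey_specs else None
        ),
        "groups": [
            {"label": g.label, "period": g.period, "diet": list(g.diet), "n": g.n}
            for g in scenario.groups
        ],
        "tdf": {
            "mean_c": scenario.tdf.mean_c,
            "sd_c": scenario.tdf.sd_c,
            "mean_n": scenario.tdf.mean_n,
            "sd_n": scenario.tdf.sd_n,
        },
        "process_sd_extra": list(scenario.process_sd_extra),
        "analytical_sd": list(scenario.analytical_sd),
        "period_windows": {
            label: [start.isoformat(), end.isoformat()]
            for label, (start, end) in scenario.period_windows.items()
        },
        "seed": scenario.seed,
    }


def scenario_from_dict(cfg: dict, seed: int | None = None) -> Scenario:
    """Build a scenario from the dict schema written by :func:`scenario_to_dict`.

    ``seed`` overrides the file's seed when given.  The string ``"regime_shift"``
    (or ``{"preset": "regime_shift"}``) selects the shipped default scenario.
    """
    if cfg == "regime_shift" or cfg.get("preset") == "regime_shift":
        return regime_shift_scenario(seed if seed is not None else int(cfg.get("seed", 0) if isinstance(cfg, dict) else 0))

    def spec_f(d: dict) -> SourceSpec:
        d = dict(d)
        if "fa_alpha" in d and d["fa_alpha"] is not None:
            d["fa_alpha"] = tuple(d["fa_alpha"])
        return SourceSpec(**d)

    windows = {
        label: (dt.date.fromisoformat(a), dt.date.fromisoformat(b))
        for label, (a, b) in cfg.get(
            "period_windows",
            {"pre": ["1998-06-01", "2001-11-30"], "post": ["2002-06-01", "2006-11-30"]},
        ).items()
    }
    return Scenario(
        sources=tuple(spec_f(d) for d in cfg["sources"]),
        prey_specs=(
            tuple(spec_f(d) for d in cfg["prey_specs"]) if cfg.get("prey_specs") else None
        ),
        groups=tuple(
            GroupSpec(g["label"], g["period"], tuple(g["diet"]), g["n"]) for g in cfg["groups"]
        ),
        tdf=TDFSpec(**cfg.get("tdf", {})),
        process_sd_extra=tuple(cfg.get("process_sd_extra", (0.2, 0.2))),
        analytical_sd=tuple(cfg.get("analytical_sd", (0.11, 0.12))),
        period_windows=windows,
        seed=seed if seed is not None else int(cfg.get("seed", 0)),
    )
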