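"""Synthetic simulation scenarios and the coverage / power harness.

The named scenarios are the small-sample designs used throughout the
method's validation: a random-slope model, the same model with a null
random intercept added (in two balance configurations, and a variant with
a null fixed slope for power studies), a longitudinal design with a single
observation per subject (n_i = 1 < q = 2, where likelihood-based fitters
cannot run), and a random-intercept model used for comparison with
generalized fiducial interval software (with nonzero and null
intercept SD).

``coverage_study`` replicates generate -> Gibbs -> equal-tailed intervals
and reports per-parameter coverage of the generating truth and the median
interval length; ``power_study`` reports rejection rates of the fiducial
zero-variance test (and fixed-effect tests) under null and alternative
generating processes.  Per-replicate RNG streams are keyed by
(master seed, replicate index), so results do not depend on execution
order or on the number of workers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .model import LMEDesign, build_design
from .sampler import ChainConfig, SamplerError, gibbs_chain
from .inference import fiducial_interval, fiducial_pvalue

__all__ = [
    "ScenarioSpec",
    "StudyResult",
    "SCENARIOS",
    "get_scenario",
    "generate",
    "coverage_study",
    "power_study",
]

_LAWS = ("normal", "index")


@dataclass(frozen=True)
class ScenarioSpec:
    """A named generating process for the simulation harness.

    ``covariates`` maps column names to a sampling law: ``"normal"`` for
    i.i.d. standard-normal draws per observation, ``"index"`` for the
    1-based subject index (a deterministic longitudinal time score).
    ``fixed`` and ``random`` list the columns entering each part, with
    ``"1"`` denoting an intercept; ``sigma_js`` are the random-effect SD
    truths (entries may be 0), ``sigma`` the error SD.
    """

    name: str
    m: int
    n_i: int
    beta: tuple
    sigma_js: tuple
    sigma: float
    covariates: dict = field(default_factory=dict)
    fixed: tuple = ("1",)
    random: tuple = ("1",)

    def __post_init__(self):
        if self.m < 1 or self.n_i < 1:
            raise ValueError("m and n_i must be >= 1")
        if len(self.beta) != len(self.fixed):
            raise ValueError("beta length must match the fixed part")
        if len(self.sigma_js) != len(self.random):
            raise ValueError("sigma_js length must match the random part")
        if any(s < 0 for s in self.sigma_js) or self.sigma < 0:
            raise ValueError("standard deviations must be nonnegative")
        for col in (*self.fixed, *self.random):
            if col != "1" and self.covariates.get(col) not in _LAWS:
                raise ValueError(f"column {col!r} needs a law in {_LAWS}")

    @property
    def p(self) -> int:
        return len(self.fixed)

    @property
    def q(self) -> int:
        return len(self.random)

    def truth(self) -> dict:
        """Generating values keyed like the sampler's parameter names."""
        out = {f"beta{j}": float(b) for j, b in enumerate(self.beta)}
        out.update({f"sigma{j}": float(s) for j, s in enumerate(self.sigma_js)})
        out["sigma"] = float(self.sigma)
        return out


SCENARIOS = {
    # y_ij = b0 + z_ij g_i1 + e_ij; m=10, n_i=2
    "example1": ScenarioSpec(
        name="example1", m=10, n_i=2, beta=(0.8,), sigma_js=(0.75,), sigma=0.7,
        covariates={"z": "normal"}, fixed=("1",), random=("z",),
    ),
    # adds a null random intercept g_i0 with sd 0
    "example2": ScenarioSpec(
        name="example2", m=10, n_i=2, beta=(0.8,), sigma_js=(0.0, 0.75), sigma=0.7,
        covariates={"z": "normal"}, fixed=("1",), random=("1", "z"),
    ),
    "example2_ni4": ScenarioSpec(
        name="example2_ni4", m=5, n_i=4, beta=(0.8,), sigma_js=(0.0, 0.75), sigma=0.7,
        covariates={"z": "normal"}, fixed=("1",), random=("1", "z"),
    ),
    # power-study variant: a null fixed slope on the same z column
    "example2_fixedslope": ScenarioSpec(
        name="example2_fixedslope", m=10, n_i=2, beta=(0.8, 0.0),
        sigma_js=(0.0, 0.75), sigma=0.7,
        covariates={"z": "normal"}, fixed=("1", "z"), random=("1", "z"),
    ),
    # longitudinal n_i=1 < q=2; covariate is the subject index 1..10
    "example3": ScenarioSpec(
        name="example3", m=10, n_i=1, beta=(10.0, 0.0), sigma_js=(1.0, 1.0), sigma=1.0,
        covariates={"t": "index"}, fixed=("1", "t"), random=("1", "t"),
    ),
    # random-intercept model for the GFI comparison; delta = 0.75 and 0
    "gfi": ScenarioSpec(
        name="gfi", m=10, n_i=2, beta=(0.8, 0.5), sigma_js=(0.75,), sigma=1.0,
        covariates={"x": "normal"}, fixed=("1", "x"), random=("1",),
    ),
    "gfi_zero": ScenarioSpec(
        name="gfi_zero", m=10, n_i=2, beta=(0.8, 0.5), sigma_js=(0.0,), sigma=1.0,
        covariates={"x": "normal"}, fixed=("1", "x"), random=("1",),
    ),
}


def get_scenario(name: str) -> ScenarioSpec:
    try:
        return SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        ) from None


def load_scenario(path) -> ScenarioSpec:
    """Read a :class:`ScenarioSpec` from a JSON/YAML key-value file.

    Expected keys mirror the dataclass fields, e.g.::

        name: my_scenario
        m: 10
        n_i: 2
        beta: [0.8]
        sigma_js: [0.0, 0.75]
        sigma: 0.7
        covariates: {z: normal}
        fixed: ["1"]
        random: ["1", z]
    """
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict):
        raise ValueError(f"scenario file {path} does not hold a key-value mapping")
    return ScenarioSpec(
        name=str(payload["name"]),
        m=int(payload["m"]),
        n_i=int(payload["n_i"]),
        beta=tuple(float(b) for b in payload["beta"]),
        sigma_js=tuple(float(s) for s in payload["sigma_js"]),
        sigma=float(payload["sigma"]),
        covariates={str(k): str(v) for k, v in dict(payload.get("covariates", {})).items()},
        fixed=tuple(str(c) for c in payload.get("fixed", ("1",))),
        random=tuple(str(c) for c in payload.get("random", ("1",))),
    )


def export_replicates(spec: ScenarioSpec, R: int, master_seed: int, outdir) -> list:
    """Write the exact per-replicate datasets a coverage study would use.

    Emits ``replicate_<r>.csv`` (long format) for r = 0..R-1, generated from
    the same (master seed, replicate) RNG streams as :func:`coverage_study`,
    so external fitters can be run on identical data.  Returns the paths.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for r in range(R):
        data_rng, _ = _replicate_rngs(master_seed, r)
        table = simulate_table(spec, data_rng)
        path = outdir / f"replicate_{r}.csv"
        table.to_csv(path, index=False)
        paths.append(path)
    return paths


def simulate_table(spec: ScenarioSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Draw one long-format dataset from the scenario's generating process."""
    m, ni = spec.m, spec.n_i
    n = m * ni
    subj = np.repeat(np.arange(1, m + 1), ni)
    cols = {}
    for name, law in spec.covariates.items():
        if law == "normal":
            cols[name] = rng.standard_normal(n)
        else:  # index
            cols[name] = subj.astype(float)

    def col(cname):
        return np.ones(n) if cname == "1" else cols[cname]

    x = np.column_stack([col(c) for c in spec.fixed])
    z = np.column_stack([col(c) for c in spec.random])
    gamma = rng.standard_normal((m, spec.q)) * np.asarray(spec.sigma_js)
    e = rng.standard_normal(n) * spec.sigma
    y = x @ np.asarray(spec.beta) + np.einsum("nk,nk->n", z, gamma[subj - 1]) + e
    frame = {"y": y, "subject": subj}
    frame.update(cols)
    return pd.DataFrame(frame)


def generate(spec: ScenarioSpec, rng: np.random.Generator) -> tuple[LMEDesign, dict]:
    """Generate a dataset and assemble its design; returns (design, truth)."""
    table = simulate_table(spec, rng)
    design = build_design(
        table,
        response="y",
        group="subject",
        fixed=tuple(c for c in spec.fixed if c != "1"),
        random=tuple(c for c in spec.random if c != "1"),
        fixed_intercept="1" in spec.fixed,
        random_intercept="1" in spec.random,
    )
    return design, spec.truth()


@dataclass(frozen=True)
class StudyResult:
    """Aggregated replication results.

    For coverage studies: per-parameter coverage of the generating truth
    and median CI length.  For power studies: rejection rates at ``alpha``
    under the null and alternative processes plus the raw p-values.
    ``records`` holds one dict per replicate (seeds, endpoints, flags);
    ``failures`` lists replicates whose sampler aborted.
    """

    kind: str
    scenario: str
    replicates: int
    master_seed: int
    level: float = 0.95
    coverage: dict = field(default_factory=dict)
    median_length: dict = field(default_factory=dict)
    rejection: dict = field(default_factory=dict)
    pvalues: dict = field(default_factory=dict)
    records: list = field(default_factory=list)
    failures: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in sorted(set(self.coverage) | set(self.median_length) | set(self.rejection)):
            rows.append(
                {
                    "parameter": name,
                    "coverage": self.coverage.get(name),
                    "median_length": self.median_length.get(name),
                    "rejection_rate": self.rejection.get(name),
                }
            )
        return pd.DataFrame(rows)


def _replicate_rngs(master_seed: int, r: int):
    """Independent data stream and chain seed for replicate r."""
    data_rng = np.random.default_rng(np.random.SeedSequence((master_seed, r, 0)))
    chain_seed = int(
        np.random.SeedSequence((master_seed, r, 1)).generate_state(1)[0] % (2 ** 31)
    )
    return data_rng, chain_seed


def _coverage_one(spec: ScenarioSpec, master_seed: int, r: int,
                  config: ChainConfig, level: float) -> dict:
    data_rng, chain_seed = _replicate_rngs(master_seed, r)
    design, truth = generate(spec, data_rng)
    cfg = ChainConfig(
        chain_length=config.chain_length, warmup=config.warmup,
        thin=config.thin, c0=config.c0, seed=chain_seed,
    )
    try:
        sample = gibbs_chain(design, cfg)
    except SamplerError as exc:
        return {"replicate": r, "chain_seed": chain_seed, "error": str(exc)}
    rec = {"replicate": r, "chain_seed": chain_seed, "intervals": {}}
    for j in range(design.p):
        name = f"beta{j}"
        ci = fiducial_interval(sample, name, level=level)
        rec["intervals"][name] = _ival(ci, truth[name])
    for j in range(design.q):
        ci = fiducial_interval(sample, f"delta{j}", level=level, sd_truncate=True)
        rec["intervals"][f"sigma{j}"] = _ival(ci, truth[f"sigma{j}"])
    ci = fiducial_interval(sample, "sigma", level=level)
    rec["intervals"]["sigma"] = _ival(ci, truth["sigma"])
    return rec


def _ival(ci, truth_value):
    return {
        "lower": ci.lower,
        "upper": ci.upper,
        "length": ci.length,
        "truth": truth_value,
        "contains": bool(ci.contains(truth_value)),
    }


def coverage_study(
    spec: ScenarioSpec,
    R: int,
    config: ChainConfig,
    level: float = 0.95,
    master_seed: int = 0,
    n_jobs: int = 1,
) -> StudyResult:
    """Replicate generate -> Gibbs -> intervals; aggregate coverage and length.

    Fixed effects use plain equal-tailed intervals; random-effect SDs use
    the zero-truncated construction; the error SD interval comes from the
    sqrt of the sigma^2 draws.  Coverage is the fraction of non-failed
    replicates whose interval contains the generating value, and lengths
    are summarized by their median across replicates.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if n_jobs != 1:
        from joblib import Parallel, delayed

        records = Parallel(n_jobs=n_jobs)(
            delayed(_coverage_one)(spec, master_seed, r, config, level)
            for r in range(R)
        )
    else:
        records = [_coverage_one(spec, master_seed, r, config, level) for r in range(R)]
    failures = [rec for rec in records if "error" in rec]
    good = [rec for rec in records if "error" not in rec]
    if not good:
        raise SamplerError("every replicate failed")
    params = list(good[0]["intervals"])
    coverage = {
        name: float(np.mean([rec["intervals"][name]["contains"] for rec in good]))
        for name in params
    }
    median_length = {
        name: float(np.median([rec["intervals"][name]["length"] for rec in good]))
        for name in params
    }
    return StudyResult(
        kind="coverage",
        scenario=spec.name,
        replicates=R,
        master_seed=master_seed,
        level=level,
        coverage=coverage,
        median_length=median_length,
        records=records,
        failures=failures,
    )


def _tested_index(spec: ScenarioSpec, null: bool) -> int:
    for j, s in enumerate(spec.sigma_js):
        if (s == 0) == null:
            return j
    raise ValueError(
        f"scenario {spec.name!r} has no random-effect SD "
        f"{'equal to' if null else 'greater than'} 0"
    )


def _power_arm(spec, master_seed, r, config, delta_index):
    data_rng, chain_seed = _replicate_rngs(master_seed, r)
    design, truth = generate(spec, data_rng)
    cfg = ChainConfig(
        chain_length=config.chain_length, warmup=config.warmup,
        thin=config.thin, c0=config.c0, seed=chain_seed,
    )
    try:
        sample = gibbs_chain(design, cfg)
    except SamplerError as exc:
        return {"replicate": r, "error": str(exc)}
    rec = {
        "replicate": r,
        "p_delta": fiducial_pvalue(sample, f"delta{delta_index}", 0.0).p,
        "p_beta": {
            f"beta{j}": fiducial_pvalue(sample, f"beta{j}", 0.0).p
            for j in range(design.p)
        },
    }
    return rec


def power_study(
    spec_null: ScenarioSpec,
    spec_alt: ScenarioSpec,
    R: int,
    config: ChainConfig,
    alpha: float = 0.05,
    master_seed: int = 0,
) -> StudyResult:
    """Rejection rates of the fiducial zero-variance test under null and alt.

    The tested component in the null arm is the first random-effect SD
    equal to 0 (type-I error); in the alternative arm the first SD greater
    than 0 (power).  The test is the fiducial p-value of delta_j at 0;
    fixed-effect p-values at 0 are recorded alongside.
    """
    j_null = _tested_index(spec_null, null=True)
    j_alt = _tested_index(spec_alt, null=False)
    arms = {}
    pvals = {}
    records = []
    failures = []
    for arm, spec, j, seed_tag in (
        ("null", spec_null, j_null, 0),
        ("alt", spec_alt, j_alt, 1),
    ):
        recs = [
            _power_arm(spec, master_seed * 2 + seed_tag, r, config, j) for r in range(R)
        ]
        failures += [dict(rec, arm=arm) for rec in recs if "error" in rec]
        good = [rec for rec in recs if "error" not in rec]
        ps = np.array([rec["p_delta"] for rec in good])
        arms[arm] = float(np.mean(ps < alpha))
        pvals[arm] = ps.tolist()
        for bname in good[0]["p_beta"]:
            pb = np.array([rec["p_beta"][bname] for rec in good])
            arms[f"{arm}:{bname}"] = float(np.mean(pb < alpha))
            pvals[f"{arm}:{bname}"] = pb.tolist()
        records += [dict(rec, arm=arm) for rec in good]
    return StudyResult(
        kind="power",
        scenario=f"{spec_null.name}|{spec_alt.name}",
        replicates=R,
        master_seed=master_seed,
        level=1.0 - alpha,
        rejection=arms,
        pvalues=pvals,
        records=records,
        failures=failures,
    )
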