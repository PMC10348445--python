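"""Synthetic cohorts with planted effects for end-to-end validation.

Real network-level rsfMRI cohorts are access-restricted, so every
downstream stage of the package is exercised on synthetic data whose
ground truth is known: binary activity patterns drawn from group-specific
Boltzmann (Ising) distributions, continuous node signals obtained by
adding Gaussian noise around the ±1 patterns, AR(1) fixtures with
controllable timescales, and subject-level symptom scores linearly
coupled (plus noise) to planted dynamics features so that correlation
and mediation stages have a known answer.

Subject heterogeneity enters in two ways: optional i.i.d. Gaussian
jitter on (h, J), and an optional *instability plant* — a latent
per-subject factor u that scales down the fields and couplings of one
target node (factor ``exp(−gain·u)``).  Subjects with higher u have a
faster-flipping target node (shorter intrinsic timescale) and a flatter
landscape around it (more frequent indirect transitions), creating a
true local-timescale → global-dynamics → symptom mediation chain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .landscape import enumerate_energies
from .mem import MEMParameters, boltzmann_distribution
from .dynamics import metropolis_random_walk, parse_template, subject_dynamics
from .patterns import check_enumerable, pattern_matrix, code_to_pattern
from .timescale import timescale_map

__all__ = [
    "GroundTruthModel",
    "EffectSpec",
    "InstabilityPlant",
    "SyntheticCohort",
    "make_ising_model",
    "make_attractor_model",
    "sample_patterns_exact",
    "sample_patterns_mcmc",
    "binary_to_continuous",
    "generate_ar1_series",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "default_study_spec",
]


@dataclass
class GroundTruthModel:
    """A known Ising model used as a generator of binary patterns."""

    n_nodes: int
    h: np.ndarray
    J: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        if self.n_nodes < 1 or self.h.shape != (self.n_nodes,):
            raise ValueError("h must have length n_nodes")
        if self.J.shape != (self.n_nodes, self.n_nodes):
            raise ValueError("J must be n_nodes x n_nodes")
        if not np.allclose(self.J, self.J.T):
            raise ValueError("J must be symmetric")
        if np.abs(np.diag(self.J)).max(initial=0.0) > 0:
            raise ValueError("J must have zero diagonal")

    def params(self) -> MEMParameters:
        return MEMParameters(h=self.h.copy(), J=self.J.copy(), order="pairwise")


def make_ising_model(
    n_nodes: int,
    field_scale: float,
    coupling_scale: float,
    seed: int | None = None,
    label: str = "",
) -> GroundTruthModel:
    """Random model: h ~ U[−field_scale, field_scale] i.i.d., J likewise on
    the upper triangle, symmetrized with zero diagonal."""
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if field_scale < 0 or coupling_scale < 0:
        raise ValueError("scales must be nonnegative")
    rng = np.random.default_rng(seed)
    h = rng.uniform(-field_scale, field_scale, size=n_nodes)
    J = np.zeros((n_nodes, n_nodes))
    iu = np.triu_indices(n_nodes, k=1)
    J[iu] = rng.uniform(-coupling_scale, coupling_scale, size=iu[0].shape[0])
    J = J + J.T
    return GroundTruthModel(n_nodes=n_nodes, h=h, J=J, label=label)


def make_attractor_model(
    stored_patterns: np.ndarray,
    coupling_strength: float = 1.0,
    field: np.ndarray | float = 0.0,
    label: str = "",
) -> GroundTruthModel:
    """Hebbian model storing given ±1 patterns as attractors.

    ``J = (c/N) Σ_μ ξ_μ ξ_μᵀ`` (zero diagonal) makes each stored pattern
    and its global flip a candidate local minimum, so storing 3 patterns
    on 7 nodes typically yields the six-minima landscape used in the
    default study; a small field breaks the ±pair degeneracy so minima
    have distinct energies.
    """
    xi = np.asarray(stored_patterns, dtype=float)
    if xi.ndim != 2:
        raise ValueError("stored_patterns must be (n_patterns, n_nodes)")
    n = xi.shape[1]
    J = (coupling_strength / n) * (xi.T @ xi)
    np.fill_diagonal(J, 0.0)
    h = np.full(n, field, dtype=float) if np.isscalar(field) else np.asarray(field, float)
    return GroundTruthModel(n_nodes=n, h=h, J=J, label=label)


def sample_patterns_exact(
    model: GroundTruthModel, n_samples: int, seed=None
) -> np.ndarray:
    """I.i.d. draws from the exact Boltzmann distribution over 2**N patterns.

    Enumerates the distribution and inverse-samples the cumulative
    probability; returns an ``(n_samples, N)`` ±1 array.
    """
    check_enumerable(model.n_nodes)
    if n_samples < 0:
        raise ValueError("n_samples must be >= 0")
    probs = boltzmann_distribution(model.params()).probabilities
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_samples == 0:
        return np.empty((0, model.n_nodes), dtype=np.int8)
    cdf = np.cumsum(probs)
    cdf[-1] = 1.0
    codes = np.searchsorted(cdf, rng.random(n_samples), side="right")
    return pattern_matrix(model.n_nodes)[codes]


def sample_patterns_mcmc(
    model: GroundTruthModel,
    n_samples: int,
    burn_in: int = 100,
    thin: int = 1,
    seed=None,
) -> np.ndarray:
    """Temporally correlated ±1 samples via the Metropolis–Hastings walk.

    ``thin=1`` returns the raw walk after burn-in; larger ``thin`` keeps
    every ``thin``-th pattern.  The marginal law converges to the
    Boltzmann distribution.
    """
    if burn_in < 0 or thin < 1:
        raise ValueError("need burn_in >= 0 and thin >= 1")
    if n_samples == 0:
        return np.empty((0, model.n_nodes), dtype=np.int8)
    traj = metropolis_random_walk(
        model.params(),
        n_steps=burn_in + n_samples * thin,
        burn_in=burn_in,
        seed=seed,
    )
    codes = traj.codes[::thin][:n_samples]
    return pattern_matrix(model.n_nodes)[codes]


def binary_to_continuous(
    patterns: np.ndarray,
    snr: float | np.ndarray,
    seed=None,
    noise_phi: float | np.ndarray = 0.0,
) -> np.ndarray:
    """Continuous signals around ±1 patterns: pattern + noise of SD 1/snr.

    ``snr`` may be a scalar or per-node vector.  The noise is i.i.d.
    Gaussian by default; ``noise_phi`` (scalar or per-node) makes it
    AR(1) with that coefficient while keeping its stationary SD at
    1/snr.  Re-binarizing at the per-timepoint mean recovers the
    patterns with high probability at high snr.
    """
    patterns = np.asarray(patterns, dtype=float)
    T, N = patterns.shape
    snr_vec = np.broadcast_to(np.asarray(snr, dtype=float), (N,))
    if (snr_vec <= 0).any():
        raise ValueError("snr must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    phi = np.broadcast_to(np.asarray(noise_phi, dtype=float), (N,))
    if (np.abs(phi) >= 1).any():
        raise ValueError("noise_phi must lie in (-1, 1)")
    noise = np.empty((T, N))
    for j in range(N):
        sd = 1.0 / snr_vec[j]
        if phi[j] == 0.0:
            noise[:, j] = rng.normal(0.0, sd, size=T)
        else:
            noise[:, j] = generate_ar1_series(phi[j], T, seed=rng) * sd * np.sqrt(
                1 - phi[j] ** 2
            )
    return patterns + noise


def generate_ar1_series(phi: float, n_timepoints: int, seed=None) -> np.ndarray:
    """Stationary AR(1): ``x_t = φ x_{t−1} + ε_t`` with standard-normal ε.

    Initialized from the stationary law N(0, 1/(1−φ²)).
    """
    if not -1 < phi < 1:
        raise ValueError("phi must lie strictly inside (-1, 1)")
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = rng.normal(size=n_timepoints)
    x = np.empty(n_timepoints)
    x[0] = eps[0] / np.sqrt(1 - phi**2)
    for t in range(1, n_timepoints):
        x[t] = phi * x[t - 1] + eps[t]
    return x


@dataclass
class InstabilityPlant:
    """Latent subject instability factor linking local and global dynamics.

    For subjects in ``groups``, a latent ``u ~ N(0, sd)`` acts on two
    fronts: it scales the subject's whole model by ``exp(−gain·u)``
    (larger u → higher effective temperature → flatter landscape → more
    frequent indirect transitions), and it shortens the AR(1) timescale
    of the target node's signal noise, ``φ_node = clip(phi0 −
    phi_gain·u, 0.05, 0.95)`` (larger u → faster local fluctuation →
    shorter measured intrinsic timescale).  ``phi0`` below the cohort's
    baseline ``noise_phi`` also plants the group-level "short INT in one
    node of one group" contrast.
    """

    node: int
    gain: float = 0.3
    sd: float = 1.0
    groups: tuple[str, ...] = ()
    phi0: float | None = None
    phi_gain: float = 0.0
    phi_bounds: tuple[float, float] = (0.05, 0.55)
    u_clip: float = 2.0  # truncate the latent factor at ±u_clip·sd


@dataclass
class EffectSpec:
    """Full recipe of a synthetic study cohort.

    ``symptom_slopes`` maps a symptom name to ``(feature, slope,
    noise_sd)``; feature names are ``"path:<template>"`` (per-subject
    empirical frequency of that indirect-transition template under the
    subject's group ground-truth landscape), ``"int:<node name>"``
    (realized intrinsic timescale of that node's continuous signal), or
    ``"instability"`` (the latent u).  ``mediation_plant``, when given as
    ``(alpha, beta, gamma_prime)``, adds pure regression-chain columns
    ``med_x, med_m, med_y`` with unit-variance noise.
    """

    group_models: dict[str, GroundTruthModel]
    n_subjects_per_group: int = 30
    n_timepoints: int = 175
    snr: float = 5.0
    symptom_slopes: dict[str, tuple[str, float, float]] = field(default_factory=dict)
    mediation_plant: tuple[float, float, float] | None = None
    seed: int = 0
    templates: tuple[str, ...] = ()
    tr_seconds: float = 2.0
    subject_jitter_sd: float = 0.0
    instability: InstabilityPlant | None = None
    noise_phi: float = 0.0
    node_snr: tuple[float, ...] | None = None  # per-node override of snr
    mcmc_thin: int = 1  # elementary MH updates per recorded timepoint (TR)
    node_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.group_models:
            raise ValueError("need at least one group model")
        sizes = {m.n_nodes for m in self.group_models.values()}
        if len(sizes) != 1:
            raise ValueError("all group models must share n_nodes")
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        (self.n_nodes,) = sizes
        if not self.node_names:
            self.node_names = tuple(f"node{i}" for i in range(self.n_nodes))
        if len(self.node_names) != self.n_nodes:
            raise ValueError("node_names length must match n_nodes")


@dataclass
class SyntheticCohort:
    """Generated cohort: manifest, per-subject series, and ground truth."""

    manifest: pd.DataFrame
    series: dict[str, np.ndarray]
    features: pd.DataFrame  # per-subject planted/realized feature values
    spec: EffectSpec
    node_names: list[str]

    def group_subjects(self, group: str) -> list[str]:
        return list(self.manifest.loc[self.manifest["group"] == group, "subject_id"])


def _feature_value(
    name: str,
    summary,
    tmap,
    u: float,
    node_names: list[str],
) -> float:
    if name == "instability":
        return u
    if name.startswith("path:"):
        template = parse_template(name[5:])
        return summary.path_freq[template.name]
    if name.startswith("int:"):
        unit = name[4:]
        if unit not in node_names:
            raise ValueError(f"unknown node {unit!r} in feature {name!r}")
        return tmap.value(unit)
    raise ValueError(f"unknown feature name {name!r}")


def generate_cohort(spec: EffectSpec) -> SyntheticCohort:
    """Generate a full synthetic cohort from an :class:`EffectSpec`.

    Per subject: draw the latent instability factor (if planted), build
    the subject-level model (group model, instability scaling, optional
    jitter), sample ``T`` temporally correlated binary patterns by MCMC,
    convert to continuous signals, record realized dynamics/timescale
    features against the *group* ground-truth landscape, and emit
    symptom scores as slope·feature + noise.  Everything derives from
    one master seed through a documented SeedSequence spawn, so the
    cohort is bit-reproducible.
    """
    # validate feature references before doing any work
    needed_features = {f for (f, _, _) in spec.symptom_slopes.values()}
    for name in needed_features:
        if not (
            name == "instability" or name.startswith("path:") or name.startswith("int:")
        ):
            raise ValueError(f"unknown feature name {name!r} in symptom_slopes")

    groups = sorted(spec.group_models)
    template_texts = list(spec.templates)
    for name in needed_features:  # symptom features imply their templates
        if name.startswith("path:") and name[5:] not in template_texts:
            template_texts.append(name[5:])
    templates = [parse_template(t) for t in template_texts]
    basins_by_group = {}
    for g in groups:
        scape = enumerate_energies(
            spec.group_models[g].params(), node_names=list(spec.node_names)
        )
        basins_by_group[g] = scape.basins()

    n_total = len(groups) * spec.n_subjects_per_group
    children = np.random.SeedSequence(spec.seed).spawn(n_total + 1)
    med_rng = np.random.default_rng(children[-1])

    manifest_rows = []
    feature_rows = []
    series: dict[str, np.ndarray] = {}
    idx = 0
    for g in groups:
        base = spec.group_models[g]
        for s in range(spec.n_subjects_per_group):
            rng = np.random.default_rng(children[idx])
            subject_id = f"{g}-{s:03d}"
            u = 0.0
            h = base.h.copy()
            J = base.J.copy()
            node_phi = np.full(base.n_nodes, spec.noise_phi, dtype=float)
            plant = spec.instability
            if plant is not None and g in plant.groups:
                lim = plant.u_clip * plant.sd
                u = float(np.clip(rng.normal(0.0, plant.sd), -lim, lim))
                scale = float(np.exp(-plant.gain * u))
                h *= scale
                J *= scale
                phi0 = spec.noise_phi if plant.phi0 is None else plant.phi0
                node_phi[plant.node] = float(
                    np.clip(phi0 - plant.phi_gain * u, *plant.phi_bounds)
                )
            if spec.subject_jitter_sd > 0:
                h = h + rng.normal(0.0, spec.subject_jitter_sd, size=h.shape)
                dJ = rng.normal(0.0, spec.subject_jitter_sd, size=J.shape)
                dJ = np.triu(dJ, k=1)
                J = J + dJ + dJ.T
            subject_model = GroundTruthModel(
                n_nodes=base.n_nodes, h=h, J=J, label=subject_id
            )
            patterns = sample_patterns_mcmc(
                subject_model,
                spec.n_timepoints,
                burn_in=200,
                thin=spec.mcmc_thin,
                seed=rng,
            )
            snr = spec.node_snr if spec.node_snr is not None else spec.snr
            signals = binary_to_continuous(
                patterns, snr=snr, seed=rng, noise_phi=node_phi
            )
            series[subject_id] = signals

            summary = (
                subject_dynamics(
                    patterns, basins_by_group[g], templates=templates,
                    subject_id=subject_id,
                )
                if templates
                else None
            )
            tmap = timescale_map(
                signals,
                tr_seconds=spec.tr_seconds,
                unit_ids=list(spec.node_names),
                subject_id=subject_id,
            )
            feat = {"subject_id": subject_id, "group": g, "instability": u}
            if summary is not None:
                for name, freq in summary.path_freq.items():
                    feat[f"pathfreq:{name}"] = freq
            for name in spec.node_names:
                feat[f"int:{name}"] = tmap.value(name)
            feature_rows.append(feat)

            row = {"subject_id": subject_id, "group": g}
            for symptom, (fname, slope, noise_sd) in spec.symptom_slopes.items():
                value = _feature_value(fname, summary, tmap, u, list(spec.node_names))
                row[symptom] = slope * value + float(rng.normal(0.0, noise_sd))
            if spec.mediation_plant is not None:
                alpha, beta, gamma_prime = spec.mediation_plant
                x = float(med_rng.normal())
                m = alpha * x + float(med_rng.normal())
                y = gamma_prime * x + beta * m + float(med_rng.normal())
                row.update({"med_x": x, "med_m": m, "med_y": y})
            manifest_rows.append(row)
            idx += 1

    return SyntheticCohort(
        manifest=pd.DataFrame(manifest_rows),
        series=series,
        features=pd.DataFrame(feature_rows),
        spec=spec,
        node_names=list(spec.node_names),
    )


# ---------------------------------------------------------------------------
# cohort I/O


def write_cohort(cohort: SyntheticCohort, directory) -> Path:
    """Write ``manifest.csv``, one ``sub-<id>.tsv`` per subject, ``truth.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cohort.manifest.to_csv(directory / "manifest.csv", index=False)
    for subject_id, signals in cohort.series.items():
        frame = pd.DataFrame(signals, columns=cohort.node_names)
        frame.to_csv(directory / f"sub-{subject_id}.tsv", sep="\t", index=False)
    spec = cohort.spec
    truth = {
        "spec": {
            "groups": {
                g: {"h": m.h.tolist(), "J": m.J.tolist(), "label": m.label}
                for g, m in spec.group_models.items()
            },
            "n_subjects_per_group": spec.n_subjects_per_group,
            "n_timepoints": spec.n_timepoints,
            "snr": spec.snr,
            "symptom_slopes": {
                k: list(v) for k, v in spec.symptom_slopes.items()
            },
            "mediation_plant": list(spec.mediation_plant)
            if spec.mediation_plant
            else None,
            "seed": spec.seed,
            "templates": list(spec.templates),
            "tr_seconds": spec.tr_seconds,
            "subject_jitter_sd": spec.subject_jitter_sd,
            "instability": asdict(spec.instability) if spec.instability else None,
            "noise_phi": spec.noise_phi,
            "node_names": list(spec.node_names),
        },
        "features": cohort.features.to_dict(orient="records"),
    }
    with open(directory / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return directory


def read_cohort(directory) -> tuple[pd.DataFrame, dict[str, np.ndarray], list[str]]:
    """Read a cohort directory: (manifest, subject series, node names)."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    series: dict[str, np.ndarray] = {}
    node_names: list[str] = []
    for subject_id in manifest["subject_id"]:
        frame = pd.read_csv(directory / f"sub-{subject_id}.tsv", sep="\t")
        node_names = list(frame.columns)
        series[str(subject_id)] = frame.to_numpy(dtype=float)
    return manifest, series, node_names


# ---------------------------------------------------------------------------
# default study recipe


def default_study_spec(
    seed: int = 0,
    n_subjects_per_group: int = 30,
    n_timepoints: int = 175,
) -> EffectSpec:
    """A four-group synthetic study with planted group and symptom effects.

    Three ±1 patterns are stored Hebbian-style on seven nodes, giving
    every group the same six local minima (states A–F, the stored
    patterns and their global flips) under a weak symmetry-breaking
    field.  Groups then differ in landscape depth:

    - ``control``: the base model;
    - ``deepened``: parameters scaled up — deeper stable states, fewer
      indirect transitions (overly stable dynamics);
    - ``flattened``: parameters scaled down plus a weakened target node
      — shallower landscape, frequent indirect transitions, and a
      shorter intrinsic timescale at the target node (unstable
      dynamics);
    - ``mixed``: intermediate scaling.

    The instability plant on the ``flattened`` group couples a latent
    subject factor to the target node, and the ``hyperactivity`` symptom
    loads on the A–[C/D–E/F]–B path frequency, creating the full
    INT → path-frequency → symptom mediation chain.
    """
    stored = np.array(
        [
            [+1, +1, +1, -1, -1, -1, -1],
            [-1, -1, +1, +1, +1, -1, +1],
            [+1, -1, -1, -1, +1, +1, +1],
        ]
    )
    # symmetry-breaking field chosen so that all four group landscapes share
    # the same six minima with the same stable/shallow/unstable pair
    # structure ({a,b}, {c,d}, {e,f} over the same pattern codes) and wide
    # energy gaps at the pair boundaries, so the state sets survive fitting
    # noise in the pooled group fits
    bias = np.array([0.116, -0.218, 0.111, -0.208, 0.266, 0.248, 0.291])
    target_node = 2  # the "dan" node carries the planted instability

    def scaled(scale: float, node_scale: float, label: str) -> GroundTruthModel:
        base = make_attractor_model(stored, coupling_strength=1.4, field=0.0)
        h = scale * bias.copy()
        J = scale * base.J
        h[target_node] *= node_scale
        J[target_node, :] *= node_scale
        J[:, target_node] *= node_scale
        return GroundTruthModel(n_nodes=7, h=h, J=J, label=label)

    groups = {
        "control": scaled(1.0, 1.0, "control"),
        "deepened": scaled(1.3, 1.0, "deepened"),
        "flattened": scaled(0.5, 0.85, "flattened"),
        "mixed": scaled(0.8, 1.0, "mixed"),
    }
    templates = ("A|C,D|B", "~A|C,D|E,F|B", "A|C,D,E,F|B")
    return EffectSpec(
        group_models=groups,
        n_subjects_per_group=n_subjects_per_group,
        n_timepoints=n_timepoints,
        snr=2.0,
        symptom_slopes={
            "hyperactivity": ("path:A|C,D,E,F|B", 300.0, 0.8),
            "sociality": ("path:A|C,D|B", -300.0, 0.8),
        },
        mediation_plant=(0.8, 0.7, 0.0),
        seed=seed,
        templates=templates,
        tr_seconds=2.0,
        noise_phi=0.8,
        node_snr=(2.0, 2.0, 1.0, 2.0, 2.0, 2.0, 2.0),  # noisier dan channel
        instability=InstabilityPlant(
            node=target_node,
            gain=0.6,
            sd=1.0,
            groups=("flattened",),
            phi0=0.2,
            phi_gain=0.3,
        ),
        mcmc_thin=4,
        node_names=("visual", "smn", "dan", "van", "limbic", "fpcn", "dmn"),
    )
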