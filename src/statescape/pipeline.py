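"""End-to-end study orchestration over a cohort directory.

Given a directory of per-subject signal matrices plus a manifest, the
pipeline (1) binarizes and pools each group's signals and fits the
pairwise MEM, (2) derives each group's energy landscape and simulates
its random-walk dynamics, (3) matches brain states across groups against
a reference group by pattern similarity, (4) computes per-subject
empirical dynamics features and intrinsic timescales, and (5) runs the
configured group statistics (contrasts, correlations, mediations) with
multiple-comparison control.  All randomness flows from one config seed.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binarize import binarize
from .dynamics import (
    PathTemplate,
    metropolis_random_walk,
    parse_template,
    patterns_to_states,
    subject_dynamics,
    transition_statistics,
)
from .groupstats import (
    Mediation,
    bh_fdr,
    bonferroni,
    pearson_correlation,
    two_sample_t,
)
from .landscape import EnergyLandscape
from .mem import PairwiseMaxEnt, PairwiseMaxEntResults
from .simulate import read_cohort
from .timescale import timescale_map

logger = logging.getLogger("statescape.pipeline")

__all__ = [
    "StudyConfig",
    "StateCorrespondence",
    "GroupLandscapeResult",
    "run_group_landscape",
    "match_states",
    "run_full_study",
]


@dataclass
class StudyConfig:
    """Declarative configuration of a full study run.

    ``correlations`` entries are ``{"group", "x", "y"}`` with feature
    column names of the cohort table (``pathfreq:<template name>``,
    ``int:<node>``, or symptom columns); ``mediations`` entries add a
    mediator ``"m"``.
    """

    cohort_dir: str = "."
    output_dir: str = "results"
    binarization_mode: str = "per-timepoint-mean"
    learning_rate: float = 0.2
    # empirical moments carry sampling error far above 1e-6; the tighter
    # 1e-8 default of fit_pairwise_mem is meant for exact-moment fits
    tol: float = 1e-6
    max_iter: int = 200_000
    n_steps: int = 100_000
    burn_in: int = 100
    seed: int = 0
    templates: list = field(
        default_factory=lambda: ["A|C,D|B", "A|C,D|E,F|B", "A|C|F|B"]
    )
    tr_seconds: float = 2.0
    q: float = 0.05
    n_boot: int = 5000
    reference_group: str = "control"
    min_accuracy_percent: float = 80.0
    correlations: list = field(default_factory=list)
    mediations: list = field(default_factory=list)

    def validate(self) -> None:
        if not 0 < self.q < 1:
            raise ValueError("q must lie in (0, 1)")
        if self.n_boot < 1 or self.max_iter < 1:
            raise ValueError("n_boot and max_iter must be positive")
        if not 0 <= self.burn_in < self.n_steps:
            raise ValueError("need 0 <= burn_in < n_steps")
        if self.binarization_mode not in (
            "per-timepoint-mean",
            "per-node-temporal-mean",
        ):
            raise ValueError(f"unknown binarization mode {self.binarization_mode!r}")
        for t in self.templates:
            parse_template(t)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        config = cls(**payload)
        config.validate()
        return config

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class GroupLandscapeResult:
    """Fitted model, landscape and simulated dynamics of one group."""

    group: str
    fit: PairwiseMaxEntResults
    landscape: EnergyLandscape
    simulated: "object"  # TransitionSummary
    walk_seed: int

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "model": self.fit.to_dict(),
            "landscape": self.landscape.to_dict(),
            "simulated": self.simulated.to_dict(),
            "walk_seed": self.walk_seed,
        }


@dataclass
class StateCorrespondence:
    """Greedy similarity matching of minima across groups.

    ``mapping[group]`` maps the group's own state labels to the
    reference group's canonical labels; ``similarity[group]`` carries
    the Pearson r between the matched minima patterns.
    """

    reference: str
    mapping: dict[str, dict[str, str]]
    similarity: dict[str, dict[str, float]]
    unmatched: dict[str, list[str]]

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "mapping": self.mapping,
            "similarity": self.similarity,
            "unmatched": self.unmatched,
        }


def _group_templates(
    templates: list[PathTemplate], basins
) -> tuple[list[PathTemplate], list[str]]:
    """Keep templates whose states all exist in this landscape."""
    available = set(basins.state_labels)
    kept, skipped = [], []
    for t in templates:
        states = {t.endpoints[0], t.endpoints[1], *(s for b in t.interior_blocks for s in b)}
        if states <= available:
            kept.append(t)
        else:
            skipped.append(t.name)
    return kept, skipped


def run_group_landscape(
    subject_signals: list[np.ndarray],
    config: StudyConfig,
    group: str = "group",
    node_names: list[str] | None = None,
    walk_seed: int | None = None,
    templates: list[PathTemplate] | None = None,
) -> GroupLandscapeResult:
    """Group-level pipeline stage: binarize → pool → fit → landscape → walk."""
    if not subject_signals:
        raise ValueError("need at least one subject")
    model = PairwiseMaxEnt.from_continuous(
        subject_signals, mode=config.binarization_mode, node_names=node_names
    )
    fit = model.fit(
        learning_rate=config.learning_rate, tol=config.tol, max_iter=config.max_iter
    )
    diag = fit.diagnostics
    if diag.accuracy_percent is not None:
        logger.info(
            "group %s: fit accuracy %.2f%% (D1=%.4g, D2=%.4g)",
            group,
            diag.accuracy_percent,
            diag.d1,
            diag.d2,
        )
        if diag.accuracy_percent < config.min_accuracy_percent:
            logger.warning(
                "group %s: fit accuracy %.2f%% below configured threshold %.1f%%",
                group,
                diag.accuracy_percent,
                config.min_accuracy_percent,
            )
    scape = fit.landscape()
    basins = scape.basins()
    if walk_seed is None:
        walk_seed = config.seed
    traj = metropolis_random_walk(
        scape, n_steps=config.n_steps, burn_in=config.burn_in, seed=walk_seed
    )
    seq = patterns_to_states(traj, basins)
    if templates is None:
        templates = [parse_template(t) for t in config.templates]
    kept, skipped = _group_templates(templates, basins)
    if skipped:
        logger.warning("group %s: templates %s reference absent states", group, skipped)
    summary = transition_statistics(seq, templates=kept)
    return GroupLandscapeResult(
        group=group, fit=fit, landscape=scape, simulated=summary, walk_seed=walk_seed
    )


def _pattern_r(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two ±1 activity patterns."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        # all-active/all-inactive patterns: fall back to sign agreement
        return float(np.mean(a * b))
    return float(np.corrcoef(a, b)[0, 1])


def match_states(
    landscapes: dict[str, EnergyLandscape], reference: str
) -> StateCorrespondence:
    """Match each group's minima to the reference group's canonical states.

    Greedy maximum-similarity assignment on Pearson r between minima
    patterns, ties broken by energy rank; minima left over when counts
    differ are reported as unmatched.
    """
    if reference not in landscapes:
        raise ValueError(f"reference group {reference!r} not among landscapes")
    ref_minima = landscapes[reference].local_minima()
    mapping: dict[str, dict[str, str]] = {}
    similarity: dict[str, dict[str, float]] = {}
    unmatched: dict[str, list[str]] = {}
    for group, scape in landscapes.items():
        minima = scape.local_minima()
        pairs = []
        for gi, gm in enumerate(minima):
            for ri, rm in enumerate(ref_minima):
                r = _pattern_r(gm.pattern, rm.pattern)
                pairs.append((-r, gi, ri))
        pairs.sort()
        gmap: dict[str, str] = {}
        gsim: dict[str, float] = {}
        used_g, used_r = set(), set()
        for neg_r, gi, ri in pairs:
            if gi in used_g or ri in used_r:
                continue
            used_g.add(gi)
            used_r.add(ri)
            gmap[minima[gi].state_label] = ref_minima[ri].state_label
            gsim[minima[gi].state_label] = -neg_r
        mapping[group] = gmap
        similarity[group] = gsim
        unmatched[group] = [
            m.state_label for i, m in enumerate(minima) if i not in used_g
        ]
    return StateCorrespondence(
        reference=reference, mapping=mapping, similarity=similarity, unmatched=unmatched
    )


def canonical_basins(
    scape: EnergyLandscape, mapping: dict[str, str]
) -> "object":
    """Relabel a landscape's basin map into canonical (reference) letters.

    ``mapping`` maps the group's own state letters to the reference
    group's; minima without a match keep unique fresh letters so they
    never collide with canonical ones.
    """
    from dataclasses import replace
    from .landscape import BasinMap

    basins = scape.basins()
    used = set(mapping.values())
    fresh = (c for c in "GHIJKLMNOPQRSTUVWXYZ" if c not in used)
    minima = []
    for m in basins.minima:
        canon = mapping.get(m.state_label)
        if canon is None:
            canon = next(fresh)
        minima.append(replace(m, label=canon.lower()))
    return BasinMap(
        minima=minima,
        assignment=basins.assignment,
        ambiguous=basins.ambiguous,
        descent_rule=basins.descent_rule,
    )


def _build_cohort_table(
    manifest: pd.DataFrame,
    series: dict[str, np.ndarray],
    basins_by_group: dict[str, "object"],
    templates: list[PathTemplate],
    config: StudyConfig,
    node_names: list[str],
) -> tuple[pd.DataFrame, list[dict]]:
    """Per-subject empirical dynamics + timescale features, with exclusions."""
    rows = []
    failures: list[dict] = []
    for _, mrow in manifest.iterrows():
        subject_id = str(mrow["subject_id"])
        group = str(mrow["group"])
        try:
            signals = series[subject_id]
            basins = basins_by_group[group]
            binary = binarize(
                signals, mode=config.binarization_mode, node_names=node_names,
                subject_id=subject_id,
            )
            kept, _ = _group_templates(templates, basins)
            summary = subject_dynamics(
                binary.values, basins, templates=kept, subject_id=subject_id
            )
            tmap = timescale_map(
                signals,
                tr_seconds=config.tr_seconds,
                unit_ids=node_names,
                subject_id=subject_id,
            )
        except Exception as exc:  # failing subject: exclude and log
            failures.append({"subject_id": subject_id, "reason": str(exc)})
            logger.warning("excluding subject %s: %s", subject_id, exc)
            continue
        row = dict(mrow)
        row["subject_id"] = subject_id
        for name, freq in summary.path_freq.items():
            row[f"pathfreq:{name}"] = freq
        for unit in node_names:
            row[f"int:{unit}"] = tmap.value(unit)
        rows.append(row)
    table = pd.DataFrame(rows)
    # partial-failure policy: a group losing half its subjects aborts the run
    for group, total in manifest.groupby("group").size().items():
        surviving = int((table["group"] == group).sum()) if len(table) else 0
        if surviving < 0.5 * total:
            raise RuntimeError(
                f"group {group}: only {surviving}/{total} subjects survived"
            )
    return table, failures


def _group_statistics(
    table: pd.DataFrame,
    config: StudyConfig,
    templates: list[PathTemplate],
    node_names: list[str],
) -> dict:
    """Contrasts vs the reference group, plus configured correlations/mediations."""
    reference = config.reference_group
    groups = sorted(g for g in table["group"].unique() if g != reference)
    ref_rows = table[table["group"] == reference]
    results: dict = {"path_contrasts": [], "int_contrasts": [], "correlations": [],
                     "mediations": []}

    # path-frequency contrasts: Bonferroni within the template x group family
    path_tests = []
    for template, group in itertools.product(templates, groups):
        col = f"pathfreq:{template.name}"
        if col not in table.columns:
            continue
        a = table.loc[table["group"] == group, col].dropna()
        b = ref_rows[col].dropna()
        if len(a) < 2 or len(b) < 2:
            continue
        try:
            res = two_sample_t(a, b)
        except ValueError:
            continue
        path_tests.append((template.name, group, res))
    if path_tests:
        adjusted = bonferroni([r.p_raw for _, _, r in path_tests])
        for (name, group, res), p_adj in zip(path_tests, adjusted):
            res.p_adjusted = float(p_adj)
            results["path_contrasts"].append(
                {"template": name, "group": group, "vs": reference, **res.to_dict()}
            )

    # per-node timescale contrasts: BH-FDR across nodes within each group pair
    for group in groups:
        tests = []
        for unit in node_names:
            col = f"int:{unit}"
            a = table.loc[table["group"] == group, col].dropna()
            b = ref_rows[col].dropna()
            if len(a) < 2 or len(b) < 2:
                continue
            try:
                res = two_sample_t(a, b)
            except ValueError:
                continue
            tests.append((unit, res))
        if not tests:
            continue
        adjusted, reject = bh_fdr([r.p_raw for _, r in tests], q=config.q)
        for (unit, res), p_adj, rej in zip(tests, adjusted, reject):
            res.p_adjusted = float(p_adj)
            results["int_contrasts"].append(
                {
                    "node": unit,
                    "group": group,
                    "vs": reference,
                    "significant_fdr": bool(rej),
                    **res.to_dict(),
                }
            )

    # configured correlations, Bonferroni over the configured family
    corr_entries = []
    for entry in config.correlations:
        sub = table[table["group"] == entry["group"]]
        try:
            x = sub[entry["x"]].to_numpy(dtype=float)
            y = sub[entry["y"]].to_numpy(dtype=float)
            mask = np.isfinite(x) & np.isfinite(y)
            r, p, df = pearson_correlation(x[mask], y[mask])
        except (ValueError, KeyError) as exc:
            logger.warning("correlation %s skipped: %s", entry, exc)
            continue
        corr_entries.append({**entry, "r": r, "p_raw": p, "df": df})
    if corr_entries:
        adjusted = bonferroni([e["p_raw"] for e in corr_entries])
        for e, p_adj in zip(corr_entries, adjusted):
            e["p_bonferroni"] = float(p_adj)
        results["correlations"] = corr_entries

    # configured mediations
    rng_seeds = np.random.SeedSequence(config.seed).spawn(len(config.mediations))
    for entry, seed_seq in zip(config.mediations, rng_seeds):
        sub = table[table["group"] == entry["group"]]
        cols = [entry["x"], entry["m"], entry["y"]]
        try:
            data = sub[cols].to_numpy(dtype=float)
            data = data[np.isfinite(data).all(axis=1)]
            med = Mediation(data[:, 0], data[:, 1], data[:, 2]).fit(
                n_boot=config.n_boot, seed=np.random.default_rng(seed_seq)
            )
        except (ValueError, KeyError) as exc:
            logger.warning("mediation %s skipped: %s", entry, exc)
            continue
        results["mediations"].append({**entry, **med.to_dict()})
    return results


def run_full_study(config: StudyConfig) -> dict:
    """Run the complete pipeline on a cohort directory; write a results bundle.

    Returns the results dictionary; writes ``results.json``,
    ``cohort_table.csv``, ``tests.csv`` and ``run.log`` under
    ``config.output_dir``.  Reruns with the same config and cohort are
    deterministic.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(outdir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(log_handler)
    logger.setLevel(logging.INFO)
    try:
        manifest, series, node_names = read_cohort(config.cohort_dir)
        logger.info(
            "cohort: %d subjects, %d nodes, config hash %s",
            len(manifest),
            len(node_names),
            config.content_hash(),
        )
        templates = [parse_template(t) for t in config.templates]
        groups = sorted(manifest["group"].astype(str).unique())
        walk_seeds = np.random.SeedSequence(config.seed).spawn(len(groups))

        # fit every group's model and landscape first ...
        fits = {}
        for group in groups:
            ids = manifest.loc[manifest["group"] == group, "subject_id"].astype(str)
            model = PairwiseMaxEnt.from_continuous(
                [series[i] for i in ids],
                mode=config.binarization_mode,
                node_names=node_names,
            )
            fit = model.fit(
                learning_rate=config.learning_rate,
                tol=config.tol,
                max_iter=config.max_iter,
            )
            diag = fit.diagnostics
            if (
                diag.accuracy_percent is not None
                and diag.accuracy_percent < config.min_accuracy_percent
            ):
                logger.warning(
                    "group %s: fit accuracy %.2f%% below threshold %.1f%%",
                    group,
                    diag.accuracy_percent,
                    config.min_accuracy_percent,
                )
            fits[group] = fit

        # ... then match states to the reference group's canonical letters
        scapes = {g: f.landscape() for g, f in fits.items()}
        correspondence = match_states(scapes, config.reference_group)
        basins_by_group = {
            g: canonical_basins(scapes[g], correspondence.mapping[g])
            for g in groups
        }

        # simulated dynamics per group under canonical state labels
        group_results: dict[str, GroupLandscapeResult] = {}
        for group, seed_seq in zip(groups, walk_seeds):
            fit = fits[group]
            scape = scapes[group]
            basins = basins_by_group[group]
            walk_seed = int(seed_seq.generate_state(1)[0] % (2**31))
            traj = metropolis_random_walk(
                scape, n_steps=config.n_steps, burn_in=config.burn_in, seed=walk_seed
            )
            seq = patterns_to_states(traj, basins)
            kept, skipped = _group_templates(templates, basins)
            if skipped:
                logger.warning(
                    "group %s: templates %s reference absent states", group, skipped
                )
            summary = transition_statistics(seq, templates=kept)
            group_results[group] = GroupLandscapeResult(
                group=group,
                fit=fit,
                landscape=scape,
                simulated=summary,
                walk_seed=walk_seed,
            )

        table, failures = _build_cohort_table(
            manifest, series, basins_by_group, templates, config, node_names
        )
        stats = _group_statistics(table, config, templates, node_names)

        results = {
            "config": asdict(config),
            "config_hash": config.content_hash(),
            "groups": {g: r.to_dict() for g, r in group_results.items()},
            "state_correspondence": correspondence.to_dict(),
            "excluded_subjects": failures,
            "statistics": stats,
        }
        with open(outdir / "results.json", "w") as fh:
            json.dump(results, fh, indent=2)
        table.to_csv(outdir / "cohort_table.csv", index=False)
        tidy = (
            stats["path_contrasts"] + stats["int_contrasts"]
        )
        pd.DataFrame(tidy).to_csv(outdir / "tests.csv", index=False)
        logger.info("results written to %s", outdir)
        results["cohort_table"] = table
        return results
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()
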