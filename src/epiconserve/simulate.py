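"""Synthetic multi-species embryo and stem-cell count matrices with known truth.

The generator emulates the design of a three-species comparison of
pluripotent epiblast development: three species (mouse-, pig- and
bovine-like) profiled at three in vivo stages (ICM, ERSE, APE) with
replicates, plus a mouse-like in vitro panel of three culture states
(2i-mESC, serum-mESC, mEpiSC) over the same orthologue universe.

Counts are negative binomial with mean/dispersion parameterisation
(variance mu + phi * mu^2), gene baselines log-normal across genes and drawn
independently per species (absolute expression diverges between species, so
samples cluster by species first, as real cross-species data do), and a
uniform per-sample library-size factor.

Planted structure, all recorded in :class:`SyntheticTruth`:

- conserved effects: genes up- or down-regulated with fold ``f`` at a stage
  transition in all three species, persisting into later stages (so an
  ICM->ERSE effect is also visible in ICM->APE, and ERSE->APE carries little
  signal of its own — the pattern the in vivo data show);
- species-specific effects: the same, in one species only;
- in vitro coupling: genes conserved across species at ICM->ERSE are planted
  in the 2i->EpiSC transition with the same direction.  A fraction
  ``transition_fraction`` of the upregulated ones are already elevated in
  serum (class ``transition``); the same fraction of downregulated ones are
  already reduced in serum;
- ground-state-restricted genes: expressed in ICM and 2i only, with a small
  leak mean elsewhere so no row is degenerate all-zero;
- in vitro-specific genes: differential in one culture transition but not in
  vivo (culture adaptation), so in vivo/in vitro overlap enrichments are not
  trivially saturated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .expression import ExpressionMatrix

#: mean used for "off" groups of ground-state-restricted genes; keeps rows
#: numerically alive without making them expressed at any sane threshold
LEAK_MEAN = 0.05


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator.  Defaults are the study conditions.

    ``n_conserved_up``/``n_conserved_down`` and ``n_species_specific`` apply
    per sequential stage transition (ICM->ERSE and ERSE->APE each get their
    own disjoint gene block).
    """

    n_orthologs: int = 2000
    species_labels: tuple[str, ...] = ("mouse", "pig", "bovine")
    stages: tuple[str, ...] = ("ICM", "ERSE", "APE")
    conditions: tuple[str, ...] = ("2i", "serum", "EpiSC")
    replicates_per_group: int = 3
    baseline_mean_log: float = 3.5
    baseline_sd_log: float = 1.0
    dispersion: float = 0.1
    library_size_range: tuple[float, float] = (0.7, 1.3)
    n_conserved_up: int = 50
    n_conserved_down: int = 50
    n_species_specific: int = 30
    planted_fold: float = 4.0
    n_ground_state: int = 10
    transition_fraction: float = 0.65
    n_invitro_specific: int = 30
    seed: int = 0

    def validate(self) -> None:
        def bad(fieldname: str, why: str) -> ConfigurationError:
            return ConfigurationError(f"invalid {fieldname}: {why}")

        if self.n_orthologs <= 0:
            raise bad("n_orthologs", "must be positive")
        if len(self.species_labels) != 3:
            raise bad("species_labels", "exactly three species required")
        if len(self.stages) != 3:
            raise bad("stages", "exactly three stages required")
        if len(self.conditions) != 3:
            raise bad("conditions", "exactly three conditions required")
        if self.replicates_per_group < 2:
            raise bad("replicates_per_group", "must be >= 2")
        if self.baseline_sd_log < 0:
            raise bad("baseline_sd_log", "must be >= 0")
        if self.dispersion <= 0:
            raise bad("dispersion", "must be > 0")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise bad("library_size_range", "must be a positive (lo, hi) pair")
        for f in ("n_conserved_up", "n_conserved_down", "n_species_specific",
                  "n_ground_state", "n_invitro_specific"):
            if getattr(self, f) < 0:
                raise bad(f, "must be >= 0")
        if self.planted_fold < 1:
            raise bad("planted_fold", "must be >= 1")
        if not (0 <= self.transition_fraction <= 1):
            raise bad("transition_fraction", "must be in [0, 1]")
        n_planted = (
            2 * (self.n_conserved_up + self.n_conserved_down)
            + 2 * 3 * self.n_species_specific
            + self.n_ground_state
            + 2 * 2 * self.n_invitro_specific
        )
        if n_planted > self.n_orthologs:
            raise bad("n_orthologs",
                      f"planted gene classes need {n_planted} genes, "
                      f"universe has only {self.n_orthologs}")


@dataclass
class SyntheticTruth:
    """Planted ground truth of one simulated study.

    ``classes`` assigns every orthologue group exactly one label among
    ``null``, ``conserved_up``, ``conserved_down``, ``species_specific``,
    ``transition``, ``ground_state_restricted`` (``detail`` qualifies it with
    the transition or species:direction).  ``invivo_mult`` and
    ``invitro_mult`` hold the planted mean multipliers per stage/condition
    (in vivo multipliers are shared across species; ground-state off-groups
    are an absolute leak mean, flagged in ``ground_state``).
    """

    classes: pd.DataFrame           # index group_id; columns class, detail
    invivo_mult: pd.DataFrame       # groups x stages, fold multipliers
    invitro_mult: pd.DataFrame      # groups x conditions
    ground_state: pd.Index          # group ids with leak-mean off-groups
    planted_fold: float

    def genes_of_class(self, klass: str, detail: str | None = None) -> set[str]:
        m = self.classes["class"] == klass
        if detail is not None:
            m &= self.classes["detail"] == detail
        return set(self.classes.index[m])

    def planted_set(self, transition: str, direction: str,
                    in_vitro: bool = False) -> set[str]:
        """Group ids planted as DE for an ordered transition, by direction.

        ``transition`` is ``"A->B"`` over stages (or conditions when
        ``in_vitro``); a gene qualifies if its planted mean multiplier
        changes in the given direction between the two endpoints.
        """
        a, b = transition.split("->")
        mult = self.invitro_mult if in_vitro else self.invivo_mult
        ratio = mult[b] / mult[a]
        mask = ratio > 1 if direction == "up" else ratio < 1
        return set(mult.index[mask])


@dataclass
class SimulatedStudy:
    """Bundle returned by :func:`simulate`."""

    species_matrices: dict[str, ExpressionMatrix]
    invitro: ExpressionMatrix
    ortholog_table: "OrthologTable"  # noqa: F821 - forward ref, see orthology
    truth: SyntheticTruth
    config: SimulationConfig


def _assign_classes(cfg: SimulationConfig, groups: pd.Index,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Partition the universe into planted classes (disjoint blocks)."""
    classes = pd.DataFrame({"class": "null", "detail": ""}, index=groups)
    order = rng.permutation(len(groups))
    cursor = 0

    def take(n: int) -> pd.Index:
        nonlocal cursor
        idx = groups[order[cursor:cursor + n]]
        cursor += n
        return idx

    t1 = f"{cfg.stages[0]}->{cfg.stages[1]}"
    t2 = f"{cfg.stages[1]}->{cfg.stages[2]}"
    for trans in (t1, t2):
        for klass, n in (("conserved_up", cfg.n_conserved_up),
                         ("conserved_down", cfg.n_conserved_down)):
            idx = take(n)
            classes.loc[idx, "class"] = klass
            classes.loc[idx, "detail"] = trans
        for sp in cfg.species_labels:
            idx = take(cfg.n_species_specific)
            classes.loc[idx, "class"] = "species_specific"
            dirs = np.where(rng.random(len(idx)) < 0.5, "up", "down")
            classes.loc[idx, "detail"] = [f"{sp}:{trans}:{d}" for d in dirs]
    idx = take(cfg.n_ground_state)
    classes.loc[idx, "class"] = "ground_state_restricted"
    classes.loc[idx, "detail"] = t1
    vt1 = f"{cfg.conditions[0]}->{cfg.conditions[1]}"
    vt2 = f"{cfg.conditions[1]}->{cfg.conditions[2]}"
    for vtrans in (vt1, vt2):
        for d in ("up", "down"):
            idx = take(cfg.n_invitro_specific)
            # culture-specific DE; in vivo these genes stay null
            classes.loc[idx, "class"] = "null"
            classes.loc[idx, "detail"] = f"invitro:{vtrans}:{d}"
    return classes


def _build_multipliers(cfg: SimulationConfig, classes: pd.DataFrame,
                       rng: np.random.Generator
                       ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Index]:
    """Planted mean multipliers per stage and condition, plus truth reclass.

    Returns (invivo groups x stages, invitro groups x conditions,
    ground-state index).  Mutates ``classes`` to promote the serum-elevated
    subset of primed-pattern genes to class ``transition``.
    """
    f = cfg.planted_fold
    stages, conds = cfg.stages, cfg.conditions
    groups = classes.index
    vivo = pd.DataFrame(1.0, index=groups, columns=list(stages))
    vitro = pd.DataFrame(1.0, index=groups, columns=list(conds))
    stage_pos = {s: i for i, s in enumerate(stages)}

    def persist(df: pd.DataFrame, idx: pd.Index, from_col: str, mult: float,
                columns: tuple[str, ...]) -> None:
        for c in columns[columns.index(from_col):]:
            df.loc[idx, c] = df.loc[idx, c] * mult

    t1 = f"{stages[0]}->{stages[1]}"
    for trans in (t1, f"{stages[1]}->{stages[2]}"):
        dest = trans.split("->")[1]
        for klass, mult in (("conserved_up", f), ("conserved_down", 1 / f)):
            idx = classes.index[(classes["class"] == klass)
                                & (classes["detail"] == trans)]
            persist(vivo, idx, dest, mult, stages)
    # species-specific multipliers are applied later, per species
    # in vitro coupling of ICM->ERSE conserved genes
    up1 = classes.index[(classes["class"] == "conserved_up")
                        & (classes["detail"] == t1)]
    down1 = classes.index[(classes["class"] == "conserved_down")
                          & (classes["detail"] == t1)]
    n_trans = int(round(cfg.transition_fraction * len(up1)))
    trans_idx = pd.Index(rng.choice(up1, size=n_trans, replace=False)) \
        if n_trans else pd.Index([], dtype=up1.dtype)
    late_up = up1.difference(trans_idx)
    vitro.loc[trans_idx, [conds[1], conds[2]]] = f     # up already in serum
    vitro.loc[late_up, conds[2]] = f                   # up only in EpiSC
    classes.loc[trans_idx, "class"] = "transition"

    n_early_down = int(round(cfg.transition_fraction * len(down1)))
    early_down = pd.Index(rng.choice(down1, size=n_early_down, replace=False)) \
        if n_early_down else pd.Index([], dtype=down1.dtype)
    vitro.loc[early_down, [conds[1], conds[2]]] = 1 / f
    vitro.loc[down1.difference(early_down), conds[2]] = 1 / f

    gs = classes.index[classes["class"] == "ground_state_restricted"]
    # in vivo: expressed in ICM only; in vitro: 2i only; plus 2i->EpiSC down
    # (handled as absolute leak means at count generation time)

    # culture-specific genes
    for vtrans, dest in ((f"{conds[0]}->{conds[1]}", conds[1]),
                         (f"{conds[1]}->{conds[2]}", conds[2])):
        for d, mult in (("up", f), ("down", 1 / f)):
            idx = classes.index[classes["detail"] == f"invitro:{vtrans}:{d}"]
            persist(vitro, idx, dest, mult, conds)
    return vivo, vitro, gs


def _species_specific_mult(cfg: SimulationConfig, classes: pd.DataFrame,
                           species: str) -> pd.DataFrame:
    """Extra multiplier matrix (groups x stages) for one species."""
    f = cfg.planted_fold
    stages = cfg.stages
    mult = pd.DataFrame(1.0, index=classes.index, columns=list(stages))
    ss = classes[classes["class"] == "species_specific"]
    for gid, detail in ss["detail"].items():
        sp, trans, d = detail.split(":")
        if sp != species:
            continue
        dest = trans.split("->")[1]
        factor = f if d == "up" else 1 / f
        for c in stages[stages.index(dest):]:
            mult.loc[gid, c] *= factor
    return mult


def _nb_counts(mean: np.ndarray, phi: float,
               rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson draw with variance mean + phi * mean^2."""
    mean = np.clip(mean, 1e-12, None)
    lam = rng.gamma(shape=1.0 / phi, scale=phi * mean)
    return rng.poisson(lam)


def simulate(config: SimulationConfig) -> SimulatedStudy:
    """Generate a full synthetic study.

    Same config (including seed) gives byte-identical output; all randomness
    flows from one :class:`numpy.random.Generator` seeded with
    ``config.seed``.
    """
    from .orthology import OrthologTable  # local import to avoid cycle

    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    groups = pd.Index([f"og{i:05d}" for i in range(cfg.n_orthologs)],
                      name="group_id")

    classes = _assign_classes(cfg, groups, rng)
    vivo_mult, vitro_mult, gs = _build_multipliers(cfg, classes, rng)

    # per-species baselines (independent: absolute expression diverges
    # between species); ground-state genes floored so they are clearly
    # expressed where on
    baselines: dict[str, np.ndarray] = {}
    for sp in cfg.species_labels:
        b = rng.lognormal(cfg.baseline_mean_log, cfg.baseline_sd_log,
                          size=cfg.n_orthologs)
        floor = np.exp(cfg.baseline_mean_log)
        b = np.where(classes.index.isin(gs), np.maximum(b, floor), b)
        baselines[sp] = b

    gs_mask = classes.index.isin(gs)
    lo, hi = cfg.library_size_range

    species_matrices: dict[str, ExpressionMatrix] = {}
    ortho_rows = {"group_id": list(groups)}
    for sp in cfg.species_labels:
        gene_ids = [f"{sp}_g{i:05d}" for i in range(cfg.n_orthologs)]
        ortho_rows[f"{sp}_gene"] = gene_ids
        ortho_rows[f"{sp}_count"] = [1] * cfg.n_orthologs
        sp_mult = vivo_mult * _species_specific_mult(cfg, classes, sp).values
        cols, meta = {}, []
        for stage in cfg.stages:
            mean_stage = baselines[sp] * sp_mult[stage].to_numpy()
            if stage != cfg.stages[0]:
                mean_stage = np.where(gs_mask, LEAK_MEAN, mean_stage)
            for rep in range(1, cfg.replicates_per_group + 1):
                lib = rng.uniform(lo, hi)
                sid = f"{sp}_{stage}_r{rep}"
                cols[sid] = _nb_counts(mean_stage * lib, cfg.dispersion, rng)
                meta.append((sid, sp, stage, rep))
        data = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
        samples = pd.DataFrame(
            meta, columns=["sample_id", "species", "stage_or_condition",
                           "replicate"]).set_index("sample_id")
        species_matrices[sp] = ExpressionMatrix(data, samples, "raw")

    # in vitro panel: mouse-like lines over the first species' gene ids
    sp0 = cfg.species_labels[0]
    gene_ids0 = [f"{sp0}_g{i:05d}" for i in range(cfg.n_orthologs)]
    cols, meta = {}, []
    for cond in cfg.conditions:
        mean_cond = baselines[sp0] * vitro_mult[cond].to_numpy()
        if cond != cfg.conditions[0]:
            mean_cond = np.where(gs_mask, LEAK_MEAN, mean_cond)
        for rep in range(1, cfg.replicates_per_group + 1):
            lib = rng.uniform(lo, hi)
            sid = f"{sp0}_{cond}_r{rep}"
            cols[sid] = _nb_counts(mean_cond * lib, cfg.dispersion, rng)
            meta.append((sid, sp0, cond, rep))
    data = pd.DataFrame(cols, index=pd.Index(gene_ids0, name="gene_id"))
    samples = pd.DataFrame(
        meta, columns=["sample_id", "species", "stage_or_condition",
                       "replicate"]).set_index("sample_id")
    invitro = ExpressionMatrix(data, samples, "raw")

    table = OrthologTable(pd.DataFrame(ortho_rows), cfg.species_labels)
    truth = SyntheticTruth(classes=classes, invivo_mult=vivo_mult,
                           invitro_mult=vitro_mult, ground_state=pd.Index(gs),
                           planted_fold=cfg.planted_fold)
    return SimulatedStudy(species_matrices, invitro, table, truth, cfg)


def config_to_dict(config: SimulationConfig) -> dict:
    """Plain-dict form for YAML/JSON round-tripping."""
    d = asdict(config)
    for k in ("species_labels", "stages", "conditions", "library_size_range"):
        d[k] = list(d[k])
    return d


def config_from_dict(d: Mapping) -> SimulationConfig:
    kwargs = dict(d)
    for k in ("species_labels", "stages", "conditions", "library_size_range"):
        if k in kwargs:
            kwargs[k] = tuple(kwargs[k])
    try:
        cfg = SimulationConfig(**kwargs)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc
    cfg.validate()
    return cfg
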