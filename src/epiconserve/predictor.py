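"""Naive/primed pluripotency predictor panels and sample scoring.

A predictor gene is an orthologue whose stage-transition behaviour is
conserved across species in vivo *and* recapitulated by the mouse culture
states in vitro.  The qualitative gene classes of the underlying biology are
codified as boolean rules over directional DE calls and expressed flags:

- ``naive``: conserved DOWN from ICM to a late epiblast stage (ERSE or APE)
  in >= ``min_species`` species, and down between 2i-mESCs and mEpiSCs;
- ``primed``: conserved UP from ICM to a late stage, and up between
  2i-mESCs and mEpiSCs;
- ``transition``: a primed-pattern gene already upregulated between 2i- and
  serum-mESCs (serum cells sit part-way from naive to primed);
- ``ground_state_restricted``: a naive-pattern gene expressed in 2i-mESCs
  but in neither serum-mESCs nor mEpiSCs.

Classes are mutually exclusive: transition genes are removed from plain
primed, ground-state-restricted genes from plain naive.

Scoring a new sample against a panel uses per-gene z-scores (across the
scored cohort) of log-scale expression: the naive score is the mean z-score
over naive-associated genes (naive + ground-state-restricted), the primed
score over primed-associated genes (primed + transition), and the call
follows the sign of their difference beyond a symmetric threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .expression import ExpressionMatrix, normalize

NAIVE_CLASSES = ("naive", "ground_state_restricted")
PRIMED_CLASSES = ("primed", "transition")


@dataclass
class PredictorGene:
    """One panel member with the evidence behind its class."""

    group_id: str
    klass: str
    evidence: dict = field(default_factory=dict)


@dataclass
class PanelScore:
    sample_id: str
    naive_score: float
    primed_score: float
    delta: float
    call: str  # naive-like | primed-like | intermediate


def derive_panel(invivo_de: Mapping[str, Mapping[str, dict[str, set]]],
                 invitro_de: Mapping[str, dict[str, set]],
                 invitro_expressed: Mapping[str, set],
                 min_species: int = 3,
                 icm_stage: str = "ICM",
                 late_stages: tuple[str, ...] = ("ERSE", "APE"),
                 conditions: tuple[str, str, str] = ("2i", "serum", "EpiSC"),
                 ) -> list[PredictorGene]:
    """Classify genes into the naive/primed panel.

    Parameters
    ----------
    invivo_de:
        ``invivo_de[species][transition][direction]`` -> set of group ids.
    invitro_de:
        ``invitro_de[transition][direction]`` -> set, transitions keyed
        ``"2i->serum"``, ``"serum->EpiSC"``, ``"2i->EpiSC"``.
    invitro_expressed:
        per condition, the set of groups called expressed.
    min_species:
        species required for in vivo conservation (default all three; 2
        admits genes conserved in only two species).
    """
    species = list(invivo_de)
    if not (2 <= min_species <= len(species)):
        raise ConfigurationError("min_species must be in [2, n_species]")
    ground, serum, epi = conditions
    vt_full = f"{ground}->{epi}"
    vt_early = f"{ground}->{serum}"
    if vt_full not in invitro_de:
        raise ValidationError(f"in vitro DE lacks transition {vt_full!r}")

    def conserved(direction: str) -> dict[str, set[str]]:
        """Per late stage, genes DE from ICM in >= min_species species."""
        out = {}
        for late in late_stages:
            trans = f"{icm_stage}->{late}"
            counts: dict[str, int] = {}
            for sp in species:
                for g in invivo_de[sp].get(trans, {}).get(direction, set()):
                    counts[g] = counts.get(g, 0) + 1
            out[late] = {g for g, c in counts.items() if c >= min_species}
        return out

    cons_up = conserved("up")
    cons_down = conserved("down")
    up_full = invitro_de[vt_full].get("up", set())
    down_full = invitro_de[vt_full].get("down", set())
    up_early = invitro_de.get(vt_early, {}).get("up", set())

    expr_ground = invitro_expressed.get(ground, set())
    expr_serum = invitro_expressed.get(serum, set())
    expr_epi = invitro_expressed.get(epi, set())

    panel: list[PredictorGene] = []
    naive_pool = set().union(*cons_down.values()) & down_full
    primed_pool = set().union(*cons_up.values()) & up_full
    for g in sorted(naive_pool):
        evidence = {
            "invivo": {late: g in cons_down[late] for late in late_stages},
            "invitro_down_2i_to_epi": True,
            "expressed": {ground: g in expr_ground, serum: g in expr_serum,
                          epi: g in expr_epi},
        }
        restricted = (g in expr_ground and g not in expr_serum
                      and g not in expr_epi)
        panel.append(PredictorGene(
            g, "ground_state_restricted" if restricted else "naive", evidence))
    for g in sorted(primed_pool):
        evidence = {
            "invivo": {late: g in cons_up[late] for late in late_stages},
            "invitro_up_2i_to_epi": True,
            "invitro_up_2i_to_serum": g in up_early,
            "expressed": {ground: g in expr_ground, serum: g in expr_serum,
                          epi: g in expr_epi},
        }
        panel.append(PredictorGene(
            g, "transition" if g in up_early else "primed", evidence))
    return panel


def transitional_fraction(epi_directional: set, serum_directional: set,
                          conserved: set | None = None) -> tuple[int, int]:
    """(k, n): of the n genes directional between 2i and EpiSC (optionally
    restricted to an in vivo conserved pool), the k already directional
    between 2i and serum — the "serum cells are a transitional state"
    statistic (reported in the source data as 29/44 up and 10/16 down).
    """
    pool = epi_directional if conserved is None else epi_directional & conserved
    return len(pool & serum_directional), len(pool)


def panel_table(panel: list[PredictorGene]) -> pd.DataFrame:
    rows = []
    for g in panel:
        row = {"group_id": g.group_id, "class": g.klass}
        ev = g.evidence
        for late, v in ev.get("invivo", {}).items():
            row[f"invivo_{late}"] = v
        row["up_2i_to_serum"] = ev.get("invitro_up_2i_to_serum", "")
        for cond, v in ev.get("expressed", {}).items():
            row[f"expressed_{cond}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def score_samples(matrix: ExpressionMatrix, panel: list[PredictorGene],
                  delta_threshold: float = 0.5,
                  min_genes_per_class: int = 3) -> list[PanelScore]:
    """Score samples for naive vs primed identity against a panel.

    Expression is taken to log2(CPM + 1) (raw input is normalised first),
    z-scored per gene across the scored samples, and averaged within the
    naive- and primed-associated gene groups.  ``delta = naive - primed``;
    calls are naive-like above ``+delta_threshold``, primed-like below
    ``-delta_threshold``, intermediate otherwise.
    """
    if matrix.unit == "raw":
        matrix = normalize(matrix, "cpm", log2_offset=1.0)
    naive_genes = [g.group_id for g in panel if g.klass in NAIVE_CLASSES]
    primed_genes = [g.group_id for g in panel if g.klass in PRIMED_CLASSES]
    present = set(matrix.genes[matrix.data.notna().all(axis=1)])
    naive_in = [g for g in naive_genes if g in present]
    primed_in = [g for g in primed_genes if g in present]
    if len(naive_in) < min_genes_per_class or len(primed_in) < min_genes_per_class:
        raise ValidationError(
            "panel coverage insufficient: "
            f"{len(naive_in)} naive / {len(primed_in)} primed genes in matrix "
            f"(need >= {min_genes_per_class} each)")

    sub = matrix.data.loc[naive_in + primed_in]
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=0).replace(0, np.nan)
    z = sub.sub(mu, axis=0).div(sd, axis=0)
    naive_score = z.loc[naive_in].mean(axis=0, skipna=True)
    primed_score = z.loc[primed_in].mean(axis=0, skipna=True)
    out = []
    for sid in matrix.sample_ids:
        ns, ps = float(naive_score[sid]), float(primed_score[sid])
        delta = ns - ps
        if delta > delta_threshold:
            call = "naive-like"
        elif delta < -delta_threshold:
            call = "primed-like"
        else:
            call = "intermediate"
        out.append(PanelScore(sid, ns, ps, delta, call))
    return out


def scores_table(scores: list[PanelScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"sample_id": s.sample_id, "naive_score": s.naive_score,
          "primed_score": s.primed_score, "delta": s.delta, "call": s.call}
         for s in scores])
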