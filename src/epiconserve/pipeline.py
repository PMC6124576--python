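"""End-to-end pipeline: orthology -> QC -> expression -> DE -> conservation
-> in vitro comparison -> predictor panel, with all stage outputs on disk.

The pipeline consumes per-species count matrices keyed by species gene ids,
one sample sheet per matrix, an orthologue table, and an in vitro matrix for
the culture states.  Every output file carries a header with the tool
version, a hash of the configuration and the seed; ``manifest.json`` echoes
the full configuration plus input checksums, so a run is reproducible from
the manifest alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, io
from .diffexpr import DECallConfig, de_sets, transition_tests
from .conservation import (conservation_profile, conserved_sets,
                           invivo_invitro_overlap)
from .errors import ConfigurationError, EpiconserveError
from .expression import (call_expressed, expressed_sets, normalize,
                         venn_regions)
from .orthology import (filter_one_to_one, load_ortholog_table, map_to_groups,
                        shared_universe)
from .predictor import derive_panel, panel_table, transitional_fraction
from .structure import flag_outliers, linkage_to_newick, pca


@dataclass
class PipelineConfig:
    """Paths and parameters of a full run."""

    species_matrices: dict[str, str]          # species -> matrix TSV
    species_sample_sheets: dict[str, str]     # species -> sample sheet TSV
    ortholog_table: str = ""
    invitro_matrix: str = ""
    invitro_sample_sheet: str = ""
    output_dir: str = "results"
    stages: tuple[str, ...] = ("ICM", "ERSE", "APE")
    conditions: tuple[str, ...] = ("2i", "serum", "EpiSC")
    de: DECallConfig = field(default_factory=DECallConfig)
    expressed_min_level: float = 1.0
    expressed_min_fraction: float = 0.5
    qc_min_median_r: float = 0.7
    mc_draws: int = 10_000
    min_species: int = 3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except FileNotFoundError as exc:
            raise ConfigurationError(f"missing config file: {path}") from exc
        de_cfg = DECallConfig(**raw.pop("de", {}))
        for k in ("stages", "conditions"):
            if k in raw:
                raw[k] = tuple(raw[k])
        try:
            cfg = cls(de=de_cfg, **raw)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from exc
        return cfg

    def validate(self) -> None:
        self.de.validate()
        if set(self.species_matrices) != set(self.species_sample_sheets):
            raise ConfigurationError(
                "species_matrices and species_sample_sheets must name the "
                "same species")
        paths = list(self.species_matrices.values()) \
            + list(self.species_sample_sheets.values()) \
            + [self.ortholog_table]
        if self.invitro_matrix:
            paths += [self.invitro_matrix, self.invitro_sample_sheet]
        for p in paths:
            if not p or not Path(p).exists():
                raise ConfigurationError(f"input path does not exist: {p!r}")

    def to_dict(self) -> dict:
        d = {
            "species_matrices": dict(self.species_matrices),
            "species_sample_sheets": dict(self.species_sample_sheets),
            "ortholog_table": self.ortholog_table,
            "invitro_matrix": self.invitro_matrix,
            "invitro_sample_sheet": self.invitro_sample_sheet,
            "output_dir": self.output_dir,
            "stages": list(self.stages),
            "conditions": list(self.conditions),
            "de": {"q_max": self.de.q_max, "fc_min": self.de.fc_min,
                   "test": self.de.test, "pseudo_mean": self.de.pseudo_mean},
            "expressed_min_level": self.expressed_min_level,
            "expressed_min_fraction": self.expressed_min_fraction,
            "qc_min_median_r": self.qc_min_median_r,
            "mc_draws": self.mc_draws,
            "min_species": self.min_species,
            "seed": self.seed,
        }
        return d


class StageFailure(EpiconserveError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sequential_transitions(stages) -> list[tuple[str, str]]:
    out = [(stages[i], stages[i + 1]) for i in range(len(stages) - 1)]
    if len(stages) >= 3:
        out.append((stages[0], stages[-1]))
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; write stage outputs under ``config.output_dir``.

    Returns a summary dict (also written as ``summary.json``).  Any stage
    failure aborts with :class:`StageFailure` naming the stage.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    # hash the analysis parameters, not where the results happen to land
    hashed = {k: v for k, v in cfg_dict.items() if k != "output_dir"}
    meta = {"config_hash": io.config_hash(hashed), "seed": config.seed}
    species = list(config.species_matrices)
    summary: dict = {"version": __version__, **meta}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except EpiconserveError as exc:
                raise StageFailure(name, exc) from exc
        return deco

    @stage("orthology")
    def _orthology():
        table = load_ortholog_table(config.ortholog_table, species)
        one = filter_one_to_one(table)
        mats = {}
        for sp in species:
            raw = io.read_matrix(config.species_matrices[sp],
                                 config.species_sample_sheets[sp])
            mats[sp] = map_to_groups(raw, one, sp)
        invitro = None
        vit_sp = None
        if config.invitro_matrix:
            raw = io.read_matrix(config.invitro_matrix,
                                 config.invitro_sample_sheet)
            # cultured lines come from one species; its sample sheet says which
            vit_sp = str(raw.samples["species"].iloc[0])
            invitro = map_to_groups(raw, one, vit_sp)
        return one, mats, invitro, vit_sp

    one, mats, invitro, invitro_species = _orthology
    universe = set(shared_universe(mats))
    summary["n_one_to_one_groups"] = len(one)
    summary["universe_size"] = len(universe)

    @stage("qc")
    def _qc():
        excluded = {}
        for sp, mat in mats.items():
            logm = normalize(mat.complete_cases(), "cpm", log2_offset=1.0)
            res = flag_outliers(logm, config.qc_min_median_r)
            excluded[sp] = res.excluded
            if res.excluded:
                drop = [s for s, _ in res.excluded]
                keep = [s for s in mat.sample_ids if s not in drop]
                mats[sp] = mat.select_samples(keep)
            p = pca(logm)
            io.write_results_tsv(
                outdir / f"qc_{sp}_pca.tsv",
                p.scores.reset_index(names="sample_id"), meta)
            io.write_results_tsv(
                outdir / f"qc_{sp}_correlation.tsv",
                res.correlation.reset_index(names="sample_id"), meta)
            nwk = linkage_to_newick(res.linkage,
                                    list(res.correlation.columns))
            (outdir / f"qc_{sp}_dendrogram.nwk").write_text(nwk + "\n")
        return excluded

    summary["qc_excluded"] = {sp: [s for s, _ in ex]
                              for sp, ex in _qc.items()}

    @stage("expression")
    def _expression():
        norm = {sp: normalize(m, "cpm") for sp, m in mats.items()}
        ex = expressed_sets(norm, config.stages, config.expressed_min_level,
                            config.expressed_min_fraction)
        venn = {}
        for st in config.stages:
            venn[st] = venn_regions({sp: ex.sets[(sp, st)] for sp in species})
        io.write_json(outdir / "expressed_venn.json", {
            st: {"regions": {"+".join(k): v
                             for k, v in venn[st]["regions"].items()},
                 "shared_fraction": venn[st]["shared_fraction"],
                 "union": venn[st]["union"]}
            for st in config.stages}, meta)
        return ex, venn

    ex_sets, venn = _expression
    summary["expressed_counts"] = {f"{sp}:{st}": len(ex_sets.sets[(sp, st)])
                                   for sp in species for st in config.stages}

    @stage("diffexpr")
    def _diffexpr():
        transitions = _sequential_transitions(config.stages)
        all_de = {}
        for sp in species:
            called = transition_tests(mats[sp], sp, transitions, config.de)
            for trans, table in called.items():
                safe = trans.replace("->", "_to_")
                io.write_de_table(outdir / f"de_{sp}_{safe}.tsv",
                                  table, trans, meta)
            all_de[sp] = {t: dict(zip(("up", "down"), de_sets(c)))
                          for t, c in called.items()}
        return all_de

    invivo_de = _diffexpr
    summary["de_counts"] = {
        f"{sp}:{t}:{d}": len(s)
        for sp, byt in invivo_de.items()
        for t, byd in byt.items() for d, s in byd.items()}

    @stage("conservation")
    def _conservation():
        profile, central = conservation_profile(
            invivo_de, universe, config.mc_draws, config.seed)
        io.write_results_tsv(outdir / "conservation_profile.tsv", profile,
                             meta)
        io.write_json(outdir / "conservation_central_genes.json",
                      {f"{t}:{d}": genes for (t, d), genes in central.items()},
                      meta)
        return profile, central

    profile, central = _conservation
    three = profile[profile["k"] == 3]
    summary["threeway_enrichment"] = {
        f"{r.transition}:{r.direction}": r.enrichment
        for r in three.itertuples()}

    if invitro is not None:
        @stage("invitro")
        def _invitro():
            c0, c1, c2 = config.conditions
            vtrans = [(c0, c1), (c1, c2), (c0, c2)]
            called = transition_tests(invitro, invitro_species, vtrans,
                                      config.de)
            vitro_de = {t: dict(zip(("up", "down"), de_sets(c)))
                        for t, c in called.items()}
            cons = conserved_sets(invivo_de, config.min_species)
            vivo_flat = {k: v for k, v in cons.items()}
            vitro_flat = {(t, d): s for t, byd in vitro_de.items()
                          for d, s in byd.items()}
            grid = invivo_invitro_overlap(vivo_flat, vitro_flat, universe)
            io.write_results_tsv(outdir / "invivo_invitro_grid.tsv", grid,
                                 meta)
            vitro_norm = normalize(invitro, "cpm")
            vitro_expr = {
                cond: call_expressed(vitro_norm, invitro_species, cond,
                                     config.expressed_min_level,
                                     config.expressed_min_fraction)
                for cond in config.conditions}
            panel = derive_panel(invivo_de, vitro_de, vitro_expr,
                                 config.min_species,
                                 icm_stage=config.stages[0],
                                 late_stages=tuple(config.stages[1:]),
                                 conditions=tuple(config.conditions))
            io.write_results_tsv(outdir / "predictor_panel.tsv",
                                 panel_table(panel), meta)
            t_full = f"{c0}->{c2}"
            t_early = f"{c0}->{c1}"
            first_trans = f"{config.stages[0]}->{config.stages[1]}"
            ku, nu = transitional_fraction(
                vitro_de[t_full]["up"], vitro_de[t_early]["up"],
                cons[(first_trans, "up")])
            kd, nd = transitional_fraction(
                vitro_de[t_full]["down"], vitro_de[t_early]["down"],
                cons[(first_trans, "down")])
            return grid, panel, (ku, nu, kd, nd)

        grid, panel, tfrac = _invitro
        summary["transitional"] = {"k_up": tfrac[0], "n_up": tfrac[1],
                                   "k_down": tfrac[2], "n_down": tfrac[3]}
        summary["panel_classes"] = {
            k: sum(1 for g in panel if g.klass == k)
            for k in ("naive", "primed", "transition",
                      "ground_state_restricted")}

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": cfg_dict,
        "inputs": {p: io.file_checksum(p)
                   for p in [*config.species_matrices.values(),
                             *config.species_sample_sheets.values(),
                             config.ortholog_table,
                             *( [config.invitro_matrix,
                                 config.invitro_sample_sheet]
                                if config.invitro_matrix else [])]},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    io.write_json(outdir / "summary.json", summary, meta)
    return summary
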