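"""Derive the naive/primed predictor panel and score culture samples.

Intersects in vivo conserved stage-transition genes with the mouse culture
transitions (2i-mESC -> serum-mESC -> mEpiSC), classifies panel genes
(naive, primed, transition, ground-state-restricted) and scores each
culture sample for naive vs primed identity.
"""

from collections import Counter

import epiconserve as ec
from epiconserve.expression import call_expressed, normalize

study = ec.simulate(ec.SimulationConfig(seed=1))
one = ec.filter_one_to_one(study.ortholog_table)
mats = {sp: ec.map_to_groups(m, one, sp)
        for sp, m in study.species_matrices.items()}
vitro = ec.map_to_groups(study.invitro, one, "mouse")

invivo_de = {sp: {t: dict(zip(("up", "down"), ec.de_sets(c)))
                  for t, c in ec.transition_tests(
                      m, sp, [("ICM", "ERSE"), ("ICM", "APE")]).items()}
             for sp, m in mats.items()}
invitro_de = {t: dict(zip(("up", "down"), ec.de_sets(c)))
              for t, c in ec.transition_tests(
                  vitro, "mouse", [("2i", "serum"), ("serum", "EpiSC"),
                                   ("2i", "EpiSC")]).items()}
norm = normalize(vitro, "cpm")
expressed = {c: call_expressed(norm, "mouse", c)
             for c in ("2i", "serum", "EpiSC")}

panel = ec.derive_panel(invivo_de, invitro_de, expressed)
print("panel classes:", dict(Counter(g.klass for g in panel)))
# naive genes drop from ICM to late epiblast in all species and from 2i to
# mEpiSC; transition genes are primed genes already up in serum; a
# ground-state-restricted gene is expressed in 2i cells only.

cons = ec.conserved_sets(invivo_de)
ku, nu = ec.transitional_fraction(invitro_de["2i->EpiSC"]["up"],
                                  invitro_de["2i->serum"]["up"],
                                  cons[("ICM->ERSE", "up")])
print(f"{ku} of {nu} conserved genes up in 2i->mEpiSC are already up in "
      "serum: serum cells sit part-way between naive and primed")

for s in ec.score_samples(vitro, panel):
    print(f"{s.sample_id:>18}: delta {s.delta:+.2f} -> {s.call}")
# 2i samples score naive-like (delta >> +0.5), mEpiSC samples primed-like,
# serum samples land in between.
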