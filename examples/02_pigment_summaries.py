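"""Pigment summary quantities and neoxanthin presence scoring.

Total carotenoids deliberately exclude lutein epoxide (a distinct cycle
member), and a taxon counts as neoxanthin-present if ANY sample of any
stage has a detectable peak.
"""

from dodder import pigments as pg

sample = pg.PigmentProfile(
    species="Cuscuta_cephalanthi", individual="A", stage="y",
    chl_a=120.0, chl_b=40.0,
    violaxanthin=8.0, antheraxanthin=2.0, zeaxanthin=3.0, neoxanthin=5.0,
    lutein=20.0, lutein_epoxide=6.0, alpha_carotene=1.5, beta_carotene=10.0,
)

print(f"total chlorophyll  : {pg.total_chlorophyll(sample):.1f} nmol/g FW")
print(f"chl a:b ratio      : {pg.chl_ab_ratio(sample):.2f}")
print(f"total carotenoids  : {pg.total_carotenoids(sample):.1f} (lutein epoxide excluded)")
print(f"VAZ pool           : {pg.vaz(sample):.1f}")
print(f"NVZ fraction       : {pg.nvz_fraction(sample):.3f} of total carotenoids")
fr = pg.normalize_by_total(sample)
print(f"lutein fraction    : {fr['lutein']:.3f} (constituent fractions sum to 1)")

states = pg.score_neoxanthin_presence(
    [sample,
     pg.PigmentProfile("Cuscuta_californica", "A", "y", neoxanthin=0.0),
     pg.PigmentProfile("Cuscuta_californica", "A", "o", neoxanthin=0.0)],
    detection_threshold=0.0,
    all_taxa=["Cuscuta_cephalanthi", "Cuscuta_californica", "Cuscuta_africana"],
)
print()
print("neoxanthin presence:", states)
print("(1 = detected somewhere, 0 = never detected, None = unsampled:")
print(" an unsampled taxon's state is inferred by the phylogenetic model)")
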