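"""Functional diversity with and without intraspecific variability.

Computes the community-weighted mean (CWM) and single-trait functional
richness (FRic, the trait range) for each of the 90 plot-communities,
once from individual measurements and once from species means, then
regresses one on the other: (1 - R^2) x 100 is the percentage of
information lost by ignoring intraspecific variability.
"""

import traitvar as tv

table = tv.generate_dataset(tv.SyntheticConfig(seed=1))

for trait in ("body_mass_g", "back_leg_length_mm"):
    fd = tv.community_fd(table, trait)
    print(f"\n{trait}: {len(fd)} communities")
    for index in ("cwm", "fric"):
        r = tv.itv_information_loss(fd, index, trait)
        print(f"  {index.upper():4s}: R^2 = {r.r2:.3f}  ->  info loss = {r.info_loss_pct:.1f}%")

# Losses stay small for CWM (averaging washes out individual noise) and
# are largest for FRic of the high-CV trait, whose range is set by
# extreme individuals.
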