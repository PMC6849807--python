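"""Environment-ontology profiles point at candidate source habitats.

Builds term-frequency profiles from per-OTU database hit annotations (the
output of a sequence-similarity + text-mining step) and prints the dense
term x OTU matrix used for heatmap plotting.
"""

from sporetrace import HitAnnotation, build_profiles, heatmap_matrix

# A sulfate-reducer enriched across the estuary: 8 close relatives, five of
# them from sediments, the rest from warm human-associated habitats.
hits = [
    HitAnnotation("T5", f"h{i}", 99.0, (term,))
    for i, term in enumerate(
        ["sediment"] * 5 + ["aerosol", "city", "compost"]
    )
]
# A marine-derived OTU whose relatives come from the hot deep biosphere;
# one hit falls below the 97% identity cutoff and is dropped.
hits += [
    HitAnnotation("M2", "h8", 98.5, ("hydrothermal vent", "marine sediment")),
    HitAnnotation("M2", "h9", 97.2, ("marine sediment",)),
    HitAnnotation("M2", "h10", 91.0, ("soil",)),
]

profiles = build_profiles(hits, min_identity=97.0)
matrix = heatmap_matrix(profiles)
print(matrix.round(1).to_string())

# Expected output (rows by total frequency, ties alphabetical):
#                      M2    T5
# marine sediment    66.7   0.0
# sediment            0.0  62.5
# hydrothermal vent  33.3   0.0
# aerosol             0.0  12.5
# city                0.0  12.5
# compost             0.0  12.5
# Each column sums to 100; the terrestrial OTU's profile is dominated by
# sediment and land-use terms, the marine OTU's by hot seabed habitats.
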