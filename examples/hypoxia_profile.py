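"""Hypoxia analysis: nuclei -> cells -> spheroid -> depth profile.

Reproduces the pimonidazole workflow on a synthetic section: identify
nuclei in the nuclear channel, grow cell territories outward from the
nuclear seeds, measure each cell's pimonidazole signal, detect the
spheroid footprint, and bin the per-cell mean intensity by distance to
the spheroid surface.
"""

from spheroquant import (
    PrimaryParams,
    SecondaryParams,
    SpheroidPhantomParams,
    generate_phantom,
    identify_primary_objects,
    identify_secondary_objects,
    identify_spheroid,
    mean_intensity_profile,
    measure_object_intensity,
    relate_objects,
)

params = SpheroidPhantomParams(seed=4)
image, truth = generate_phantom(params)

nuclei = identify_primary_objects(
    image["DAPI"],
    PrimaryParams(diameter_min_px=5, diameter_max_px=20),
)
print(f"nuclei: {len(nuclei.accepted_labels)} accepted of "
      f"{nuclei.n_objects} segmented (rest size- or border-discarded)")

cells = identify_secondary_objects(
    nuclei, image["pimonidazole"], SecondaryParams(max_expansion_px=4.0)
)
spheroid = identify_spheroid(
    image["DAPI"],
    diameter_estimate_px=2 * params.spheroid_radius_px,
    threshold_strategy="manual",
    manual_threshold=10.0,
)
print(f"spheroid equivalent diameter: {spheroid.equivalent_diameter_px:.0f} px "
      f"(true {2 * params.spheroid_radius_px:.0f})")

records = relate_objects(cells, spheroid)
feats = measure_object_intensity(cells, image["pimonidazole"])
records = records.merge(
    feats.rename(columns={"mean": "pimonidazole_mean"}), on="object_id"
)

profile = mean_intensity_profile(records, "pimonidazole", bin_width_um=50.0)
print("\ndepth bin (um)   n cells   mean pimonidazole (a.u.)")
for row in profile.to_frame().itertuples():
    value = f"{row.value:8.1f}" if row.defined else "  (empty)"
    print(f"{row.bin_start_um:4.0f}-{row.bin_end_um:<6.0f} {row.n_objects:9d}  {value}")
print("\nthe mean intensity rises with depth: oxygen falls from the "
      "surface toward the core, so pimonidazole adducts accumulate there.")
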