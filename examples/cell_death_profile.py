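"""Cell-death analysis: merged nuclear image, DRAQ7 positivity, depth profile.

Dead and dying cells take up DRAQ7; necrotic nuclei are dim in DAPI, so a
per-pixel maximum merge of the FUCCI and DRAQ7 channels provides the
comprehensive nuclear image for segmentation.  The fraction of
DRAQ7-positive nuclei per depth bin localises death inside the spheroid.
"""

from spheroquant import (
    PrimaryParams,
    SpheroidPhantomParams,
    classify_positive,
    generate_phantom,
    identify_primary_objects,
    measure_object_intensity,
    merge_channels,
    positive_fraction_profile,
    relate_objects,
)

params = SpheroidPhantomParams(seed=8)
image, truth = generate_phantom(params)

nuclear = merge_channels([image["mAG"], image["mKO2"], image["DRAQ7"]])
nuclei = identify_primary_objects(nuclear, PrimaryParams(5, 20))
print(f"nuclei from the merged image: {len(nuclei.accepted_labels)} accepted")

records = relate_objects(nuclei, truth.spheroid_mask())
feats = measure_object_intensity(nuclei, image["DRAQ7"])
records = records.merge(
    feats.rename(columns={"mean": "DRAQ7_mean"}), on="object_id"
)
flags, threshold = classify_positive(records["DRAQ7_mean"], "automatic")
records["DRAQ7_positive"] = flags
print(f"automatic (Otsu) positivity threshold: {threshold:.1f} a.u.; "
      f"{int(flags.sum())} DRAQ7+ nuclei")

profile = positive_fraction_profile(records, "DRAQ7", bin_width_um=50.0)
print("\ndepth bin (um)   n nuclei   DRAQ7+ (%)")
for row in profile.to_frame().itertuples():
    value = f"{100 * row.value:7.1f}" if row.defined else " (empty)"
    print(f"{row.bin_start_um:4.0f}-{row.bin_end_um:<6.0f} {row.n_objects:9d}  {value}")
print("\ndeath concentrates at depth: the necrotic core plus the "
      "depth-rising dying fraction the generator encodes.")
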