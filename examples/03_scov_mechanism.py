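"""The transit-delay mechanism behind the spatial coefficient of variation.

Sweeps a group ATT offset while holding true CBF fixed: once transit times
exceed the post-labelling delay, the measured map becomes spatially
heterogeneous (label stuck proximally, tissue under-supplied distally), so
GM sCoV rises while measured GM CBF falls — sCoV acts as an ATT surrogate.
"""

from aslscov import (
    AcquisitionParams,
    CohortConfig,
    average_repeats,
    build_phantom,
    calibrate_m0,
    quantify_cbf,
    roi_mean,
    roi_set_from_labels,
    spatial_cov,
    synthesize_asl,
)

params = AcquisitionParams(noise_sd=0.0)
base = CohortConfig()

print(f"PLD = {params.pld} s, base ATT = {base.att_base} s "
      f"(+{base.att_posterior} s posterior)")
print(f"{'ATT offset (s)':>14s} {'GM sCoV (%)':>12s} {'GM CBF':>8s}")
for off in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
    cfg = base.replace(att_group_offsets={**base.att_group_offsets, "control": off})
    ph = build_phantom(cfg, "control", (70.0, "f", "site_a"), seed=3)
    ds = synthesize_asl(ph, params, seed=1)
    cbf = quantify_cbf(
        average_repeats(ds.diff_volumes), calibrate_m0(ds.m0_volume, params), params
    )
    rois = roi_set_from_labels(ph.roi_labels, ph.pv_gm)
    gm = rois["gm"] & cbf.mask
    print(f"{off:14.1f} {spatial_cov(cbf.values, gm):12.2f} "
          f"{roi_mean(cbf.values, gm):8.2f}")

print("\nsCoV is monotone non-decreasing and measured CBF non-increasing "
      "in the transit delay: spatial heterogeneity of the CBF map encodes "
      "ATT without measuring it directly.")
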