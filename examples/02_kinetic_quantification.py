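"""Forward-simulate a pCASL acquisition and invert it back to CBF.

Shows the exact-inversion property of single-compartment quantification:
when every transit time is shorter than the post-labelling delay and there
is no noise, the quantified map equals the ground-truth CBF to machine
precision.  With the default noise level the recovered grey-matter mean is
close but not exact.
"""

import numpy as np

from aslscov import (
    AcquisitionParams,
    CohortConfig,
    average_repeats,
    build_phantom,
    calibrate_m0,
    quantify_cbf,
    synthesize_asl,
)

config = CohortConfig(abv_vessel=0.0)
phantom = build_phantom(config, "control", (70.0, "f", "site_a"), seed=1)

for noise in (0.0, 1.0):
    params = AcquisitionParams(noise_sd=noise)
    ds = synthesize_asl(phantom, params, seed=2)
    cbf = quantify_cbf(
        average_repeats(ds.diff_volumes),
        calibrate_m0(ds.m0_volume, params),
        params,
    )
    sel = cbf.mask & (phantom.pv_gm >= 0.25)
    err = np.abs(cbf.values[sel] - phantom.cbf_true[sel]) / phantom.cbf_true[sel]
    print(f"noise_sd={noise}: n_repeats={params.n_repeats}, "
          f"max GM relative CBF error = {err.max():.3g}, "
          f"median = {np.median(err):.3g}")

print("\nWith zero noise the quantification formula is the algebraic "
      "inverse of the forward model (error at machine precision); thermal "
      "noise leaves percent-level voxelwise error after averaging the "
      "eight repeats.")
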