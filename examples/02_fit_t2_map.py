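"""Render one subject's multi-echo stack and fit the noise-corrected T2 map.

Compares the per-compartment mean of the fitted map against the subject's
true compartment means: agreement to ~0.1 ms shows the Rician noise floor is
being absorbed by the fitted B term instead of biasing T2.
"""

from dataclasses import replace

import numpy as np

from cartt2 import (COMPARTMENTS, COMPARTMENT_LABELS, SimConfig, fit_map,
                    simulate_subject_images)

config = replace(SimConfig(), n_incidence=1, n_control=0, seed=7)
subject, field, stack = next(iter(simulate_subject_images(config)))
print(f"subject {subject.subject_id}: stack shape {stack.data.shape}, "
      f"echo times {stack.echo_times} ms")

t2map = fit_map(stack, field.labels > 0)
print(f"fitted pixels: {int(t2map.valid.sum())}, "
      f"median noise term B = {np.nanmedian(t2map.b[t2map.valid]):.2f} "
      f"(true Rician floor sqrt(2)*sigma = {np.sqrt(2)*config.noise_sigma:.2f})")
print(f"{'compartment':<16}{'true mean':>10}{'fitted mean':>12}")
for comp in COMPARTMENTS:
    sel = (field.labels == COMPARTMENT_LABELS[comp]) & t2map.valid
    print(f"{comp:<16}{field.compartment_means[comp]:>10.2f}"
          f"{t2map.t2[sel].mean():>12.2f}")
print("\nAt this high SNR the noise floor is tiny, so B is weakly identified "
      "per pixel (often 0); it becomes decisive at low SNR, where it keeps "
      "T2 unbiased.")
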