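"""Generate a synthetic vocal-tract series and inspect its ground truth.

The phantom emulates a dynamic midsagittal series: a static head with a
posterior pharyngeal wall, a soft palate that periodically contacts the
wall (velopharyngeal closures), an oscillating tongue and jaw, per-frame
six-class label maps and the true displacement field of every frame
relative to the reference frame.
"""

import numpy as np

from vtreg import PhantomSpec, generate_phantom

spec = PhantomSpec(height=64, width=64, n_frames=40, n_closures=3, seed=0)
out = generate_phantom(spec)

print(f"frames:            {out.images.shape}")
print(f"intensity range:   [{out.images.min():.2f}, {out.images.max():.2f}]")
print(f"reference frame:   {out.reference_index}")
print(f"closure runs:      {out.closure_truth.runs}")
print(f"max |displacement|: {np.abs(out.fields_to_reference).max():.1f} px")

# Each closure run is a maximal interval of frames in which at least three
# posterior soft-palate pixels touch the pharyngeal wall; the displacement
# fields warp the reference label map onto every frame.
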