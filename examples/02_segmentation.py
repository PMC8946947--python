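"""Propagate template deep-gray labels to a phantom subject and score overlap.

Registers the subject's hybrid-contrast image to the template with the
in-repo affine engine, carries the template labels back by nearest-neighbor
transport, and reports per-structure Dice against the generator's exact
truth masks.
"""

from ironmap import PhantomSpec, generate_subject, generate_template
from ironmap.hybrid_contrast import build_system, fuse, solve_weights
from ironmap.io_preproc import RegistrationConfig
from ironmap.segmentation import (
    DeformationProvider,
    mask_quality_report,
    propagate_labels,
)

subject = generate_subject(PhantomSpec(class_name="MSA-P", seed=11))
template, template_mask = generate_template()

weights = solve_weights(
    build_system(subject.t1w, subject.swi, subject.truth, template, template_mask)
)
hc = fuse(subject.t1w, subject.swi, weights)

provider = DeformationProvider.from_registration(
    hc, template, RegistrationConfig.fast()
)
dgm_mask = propagate_labels(hc, template, template_mask, provider)

report = mask_quality_report(dgm_mask, subject.truth)
for name, row in report.items():
    print(
        f"{name:16s} Dice {row['dice']:.3f}  "
        f"pred {row['pred_voxels']:6d} vox  truth {row['truth_voxels']:6d} vox  "
        f"centroid off {row['centroid_displacement_mm']:.2f} mm"
    )
print()
print("Dice near 0.9 for the putamen means the affine propagation localizes")
print("the nucleus well on these affinely jittered phantoms; the centroid")
print("displacement shows the residual placement error in millimetres.")
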