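"""Solve hybrid-contrast weights for one phantom subject and fuse the images.

Builds a paired T1w/SWI phantom, computes the ROI-mean system against the
reference template, solves the 2x2 least-squares weight problem, and checks
that the fused image reproduces the template's deep-gray contrast.
"""

from ironmap import PhantomSpec, generate_subject, generate_template, roi_mean
from ironmap.hybrid_contrast import build_system, fuse, solve_weights

subject = generate_subject(PhantomSpec(class_name="MSA-P", seed=3))
template, template_mask = generate_template()

system = build_system(subject.t1w, subject.swi, subject.truth, template, template_mask)
weights = solve_weights(system)
hc = fuse(subject.t1w, subject.swi, weights)

print(f"weights: w1 = {weights.w1:.4f}, w2 = {weights.w2:.4f}")
print(f"residual of the 2x2 solve: {weights.residual:.3g}")
print(f"template putamen mean:     {system.put_mni:8.3f}")
print(f"fused HC putamen mean:     {roi_mean(hc, subject.truth, 'putamen'):8.3f}")
print(f"template pallidum mean:    {system.pall_mni:8.3f}")
print(f"fused HC pallidum mean:    {roi_mean(hc, subject.truth, 'globus pallidus'):8.3f}")
print()
print("With a non-singular 2x2 system the residual is zero, so the HC image's")
print("putamen and pallidum means match the template targets exactly: the fused")
print("contrast has template-like deep-gray delineation while inheriting the")
print("iron sensitivity of SWI (w2 > 0 keeps iron hypointensity in the HC).")
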