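"""Extract the 178-feature radiomic vector from a phantom putamen.

Shows the per-family feature counts, the distance-parameterized GLCM names,
and how the MSA-P iron gradient moves a distance-4 co-occurrence feature
relative to a PD phantom.
"""

from collections import Counter

from ironmap import PhantomSpec, extract_all, generate_subject

msap = generate_subject(PhantomSpec(class_name="MSA-P", seed=42))
pd_subject = generate_subject(PhantomSpec(class_name="PD", seed=43))

fv_msap = extract_all(msap.swi, msap.truth, "putamen")
fv_pd = extract_all(pd_subject.swi, pd_subject.truth, "putamen")

counts = Counter(name.split("_", 1)[0] for name in fv_msap.names())
print(f"total features: {len(fv_msap)}")
for family, n in sorted(counts.items()):
    print(f"  {family:10s} {n:3d}")

print()
for name in ("glcm_Autocorrelation4", "glcm_SumAverage7", "gldm_HighGrayLevelEmphasis"):
    print(f"{name:28s} MSA-P {fv_msap[name]:9.3f}   PD {fv_pd[name]:9.3f}")
print()
print("GLCM and NGTDM families are computed at neighbor distances 1, 4 and 7")
print("(the trailing digit); the broad posterolateral gradient of the MSA-P")
print("phantom and the thin lateral slit of the PD phantom produce different")
print("co-occurrence statistics even though both putamina have the same mean")
print("signal drop.")
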