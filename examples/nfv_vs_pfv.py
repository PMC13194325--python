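"""Native vs prosthetic femoral version under two stem-seating policies.

Press-fit stems take the orientation the canal dictates, not the native
neck's.  This script measures NFV on generated native femora and PFV on
their stem-reconstructed counterparts, once with the stem version drawn
independently of the native version (the press-fit scenario) and once with
the stem seated exactly at the native version.  The Pearson correlation
between the two series separates the scenarios sharply.
"""

from femurpdm.experiments import correlation_contrast

out = correlation_contrast(n=24, seed=3)

for scenario, cmp in out.items():
    print(f"--- stem seating: {scenario}")
    print(f"  NFV  {cmp.mean_nfv:5.1f} +/- {cmp.sd_nfv:.1f} deg")
    print(f"  PFV  {cmp.mean_pfv:5.1f} +/- {cmp.sd_pfv:.1f} deg")
    print(f"  mean |NFV - PFV|  {cmp.mean_abs_diff:.1f} deg")
    print(f"  Pearson r(NFV, PFV) = {cmp.pearson_r:+.3f}")
    if scenario == "independent":
        print(f"  paired t-test p = {cmp.t_p_value:.4f}, "
              f"sign-flip permutation p = {cmp.permutation_p_value:.4f}")
print()
print("Near-zero correlation under independent seating means the native")
print("version alone cannot predict where a press-fit stem will sit.")
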