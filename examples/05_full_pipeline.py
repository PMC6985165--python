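"""Run all three analyses with one config and print the headline tables.

Equivalent to `crypsis all --seed 1 --outdir results/` from the shell.
"""

from crypsis import RunConfig, run_all

config = RunConfig(seed=1, n_perm=499, n_boot=500, n_photos_per_habitat=8)
reports = run_all(config)

print("chromatic camouflage verdicts:")
print(
    reports["chromatic_tests"][
        ["scene", "pseudo_F", "p", "mean_jnd", "ci_low", "ci_high", "verdict"]
    ].round(3).to_string(index=False)
)

print("\npattern/luminance matches (|d| < 0.8):")
pattern = reports["pattern_camouflage"]
print(
    pattern.pivot_table(index=["habitat", "animal", "background"], columns="variable",
                        values="abs_d").round(2).to_string()
)

print("\ndepth shift (chromaticity units, 0.5 m -> 10 m):")
print(reports["depth_shift"].groupby("scene")[["shift_xy", "shift_jnd"]].mean().round(4).to_string())
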