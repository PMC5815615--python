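"""Pre-kriging screening: normality, correlations, AIC choice, Moran's I.

Descriptive statistics gate the Gaussian assumption behind kriging; the AIC
table picks the cokriging covariate (altitude here); Moran's I confirms the
spatial autocorrelation that makes interpolation worthwhile at all.
"""

from dendroscape import aic_table, describe, make_trentino_like, morans_i
from dendroscape.exploratory import pearson_screen, render_pearson_table

df = make_trentino_like(seed=0).sites

d = describe(df["d2H_2013"].to_numpy())
print(f"d2H_2013: mean {d['mean']:.1f}, sd {d['sd']:.1f}, "
      f"skew {d['skewness']:.2f}, Shapiro-Wilk p = {d['shapiro_p']:.2f}")

screen = pearson_screen(
    df, ["d18O_2014", "d2H_2014"],
    ["altitude", "mean_summer_temperature", "x", "y"],
)
print(render_pearson_table(screen).to_string())

aic = aic_table(df, ["d18O_2014"], ["altitude", "mean_summer_temperature",
                                    "summer_radiation", "canopy_cover"])
print(aic.sort_values("aic").to_string(index=False))

m = morans_i(df, df["d2H_2013"].to_numpy(), n_perm=999, seed=0)
print(f"Moran's I = {m.i:.3f} (E[I] = {m.expected:.3f}), "
      f"permutation p = {m.p_perm:.3f}")
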