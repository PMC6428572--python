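{
  "seed": 20260922,
  "qx": {
    "statistic": 6.99038826768789,
    "df": 4,
    "p_value": 0.1363970340908504
  },
  "axis_latitude": {
    "statistic": 2.8313051331345602,
    "df": 1,
    "p_value": 0.09244320529702368
  },
  "tsds_curve_means": [
    -0.12617208210798153,
    -0.057885412560753885,
    -0.14732082174490121,
    0.049321487714635674,
    -0.08370637138873001
  ],
  "tsds_jackknife": {
    "rho": -0.03433590937454999,
    "se": 0.07730939998992432,
    "p_value": 0.6569440572580709
  },
  "ldsc": {
    "slope": 0.7832589283937934,
    "intercept": 11.77866122782551,
    "slope_se": 0.10308343902798014,
    "intercept_se": 2.842282389408499
  }
}
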