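{
 "unit": "percent",
 "note": "SYNTHETIC stand-in coefficients: fitted against canonical linear pyrosequencing trajectories, not the original published equations.",
 "calibration_trajectories": {
  "ASPA_CpG1": {
   "alpha": 45.0,
   "beta": -0.25
  },
  "EDARADD_CpG1": {
   "alpha": 60.0,
   "beta": -0.3
  },
  "ELOVL2_CpG4": {
   "alpha": 12.0,
   "beta": 0.55
  },
  "ELOVL2_CpG5": {
   "alpha": 15.0,
   "beta": 0.5
  },
  "ELOVL2_CpG6": {
   "alpha": 18.0,
   "beta": 0.45
  },
  "ELOVL2_CpG7": {
   "alpha": 22.0,
   "beta": 0.35
  },
  "KLF14_CpG2": {
   "alpha": 5.0,
   "beta": 0.15
  },
  "PDE4C_CpG1": {
   "alpha": 8.0,
   "beta": 0.28
  },
  "TRIM59_CpG5": {
   "alpha": 10.0,
   "beta": 0.4
  }
 },
 "clocks": [
  {
   "name": "Bekaert",
   "form": "MQR",
   "intercept": 70.4581036504,
   "terms": [
    {
     "marker": "ASPA_CpG1",
     "exponent": 1,
     "coefficient": -0.228584056212
    },
    {
     "marker": "ASPA_CpG1",
     "exponent": 2,
     "coefficient": -0.0162889313607
    },
    {
     "marker": "EDARADD_CpG1",
     "exponent": 1,
     "coefficient": -0.140468538225
    },
    {
     "marker": "EDARADD_CpG1",
     "exponent": 2,
     "coefficient": -0.00725301919804
    },
    {
     "marker": "ELOVL2_CpG6",
     "exponent": 1,
     "coefficient": 0.158989959716
    },
    {
     "marker": "ELOVL2_CpG6",
     "exponent": 2,
     "coefficient": 0.0036647753015
    },
    {
     "marker": "PDE4C_CpG1",
     "exponent": 1,
     "coefficient": 0.318174878471
    },
    {
     "marker": "PDE4C_CpG1",
     "exponent": 2,
     "coefficient": 0.0118478638257
    }
   ]
  },
  {
   "name": "Thong",
   "form": "MLR",
   "intercept": -33.5509939209,
   "terms": [
    {
     "marker": "ELOVL2_CpG6",
     "exponent": 1,
     "coefficient": 0.657737586508
    },
    {
     "marker": "KLF14_CpG2",
     "exponent": 1,
     "coefficient": 2.23635960545
    },
    {
     "marker": "PDE4C_CpG1",
     "exponent": 1,
     "coefficient": 1.31628171296
    }
   ]
  },
  {
   "name": "Garali_MQR",
   "form": "MQR",
   "intercept": -25.5476023497,
   "terms": [
    {
     "marker": "ELOVL2_CpG4",
     "exponent": 1,
     "coefficient": 0.9797101448
    },
    {
     "marker": "ELOVL2_CpG4",
     "exponent": 2,
     "coefficient": -0.00119621242551
    },
    {
     "marker": "ELOVL2_CpG5",
     "exponent": 1,
     "coefficient": 0.909592901589
    },
    {
     "marker": "ELOVL2_CpG5",
     "exponent": 2,
     "coefficient": 0.00145672251883
    }
   ]
  },
  {
   "name": "Garali_GBR",
   "form": "GBR",
   "training": {
    "seed": 2021,
    "n": 1000,
    "age_range": [
     5.0,
     91.0
    ],
    "markers": [
     "ELOVL2_CpG4",
     "ELOVL2_CpG5",
     "ELOVL2_CpG6"
    ],
    "hyperparams": {
     "n_estimators": 100,
     "max_depth": 3,
     "learning_rate": 0.1
    }
   }
  }
 ]
}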