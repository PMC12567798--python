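* Synthetic stand-in excerpt in AAindex1 flat-file format.
* Record ids are real AAindex accessions; the numeric values are
* representative reconstructions of each property, NOT the database's
* values. Bundled so the default descriptor configuration and the
* packaged selected-feature manifest resolve without the full AAindex
* database; point DescriptorConfig.aaindex_path at a genuine AAindex1
* file for faithful physicochemical values.
H CIDH920105
D Normalized average hydrophobicity scale (synthetic stand-in values)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.02   -0.42   -0.77   -1.04    0.77   -1.10   -1.14   -0.80    0.26    1.81
    1.14   -0.41    1.00    1.35   -0.09   -0.97   -0.77    1.71    1.11    1.13
//
H BHAR880101
D Average flexibility index (synthetic stand-in values)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0.357   0.529   0.463   0.511   0.346   0.493   0.497   0.544   0.323   0.462
   0.365   0.466   0.295   0.314   0.509   0.507   0.444   0.305   0.420   0.386
//
H CHAM820101
D Polarizability parameter (synthetic stand-in values)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0.046   0.291   0.134   0.105   0.128   0.180   0.151   0.000   0.230   0.186
   0.186   0.219   0.221   0.290   0.131   0.062   0.108   0.409   0.298   0.140
//
H CHAM820102
D Free energy of solution in water (synthetic stand-in values)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
  -0.368  -1.030   0.000   2.060   4.530   0.731   1.770  -0.525   0.000   0.791
   1.070   0.000   0.656   1.060  -2.240  -0.524   0.000   1.600   4.910   0.401
//
H CHOC760101
D Residue accessible surface area (synthetic stand-in values)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   115.0   225.0   160.0   150.0   135.0   180.0   190.0    75.0   195.0   175.0
   170.0   200.0   185.0   210.0   145.0   115.0   140.0   255.0   230.0   155.0
//
H BIGC670101
D Residue volume (synthetic stand-in values)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    52.6   109.1    75.7    68.4    68.3    89.7    84.7    36.3    91.9   102.0
   102.0   105.1    97.7   113.9    73.6    54.9    71.2   135.4   116.2    85.1
//
H CHAM810101
D Steric parameter (synthetic stand-in values)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.52    0.68    0.76    0.76    0.62    0.68    0.68    0.00    0.70    1.02
    0.98    0.68    0.78    0.70    0.36    0.53    0.50    0.70    0.70    0.76
//
H DAYM780201
D Relative mutability (synthetic stand-in values)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   100.0    65.0   134.0   106.0    20.0    93.0   102.0    49.0    66.0    96.0
    40.0    56.0    94.0    41.0    56.0   120.0    97.0    18.0    41.0    74.0
//
H FASG760104
D pK of the alpha-amino group (synthetic stand-in values)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    9.69    9.04    8.80    9.60   10.28    9.13    9.67    9.60    9.17    9.68
    9.60    8.95    9.21    9.13   10.60    9.15    9.10    9.39    9.11    9.62
//
H QIAN880117
D Helix formation weight (synthetic stand-in values)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    1.42    0.98    0.67    1.01    0.70    1.11    1.51    0.57    1.00    1.08
    1.21    1.16    1.45    1.13    0.57    0.77    0.83    1.08    0.69    1.06
//
H GEOR030101
D Domain linker propensity (synthetic stand-in values)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.96    1.14    1.06    1.02    0.78    1.30    1.05    1.06    1.09    0.91
    0.92    1.02    0.85    0.76    1.70    1.06    1.05    0.79    0.89    0.86
//
H RISJ880101
D Relative substitution conservation score (synthetic stand-in values)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    2.36    1.92    1.70    1.67    1.25    1.75    1.68    2.06    1.53    1.94
    2.08    1.93    1.66    1.69    1.75    2.01    1.97    1.23    1.54    2.17
//
H BEGF750101
D Conformational parameter, helix (synthetic stand-in values)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    1.29    1.00    0.81    1.10    0.79    1.07    1.49    0.63    1.33    1.05
    1.31    1.33    1.54    1.13    0.63    0.78    0.77    1.18    0.71    0.81
//
H BEGF750102
D Conformational parameter, extended strand (synthetic stand-in values)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.90    0.99    0.76    0.72    1.24    0.80    0.75    0.92    1.08    1.45
    1.02    0.77    0.97    1.32    0.75    0.95    1.21    1.14    1.25    1.49
//
H BURA740102
D Normalized frequency of extended structure (synthetic stand-in values)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.90    1.02    0.62    0.73    1.24    1.18    0.33    0.58    1.12    1.54
    1.26    0.90    1.09    1.23    0.42    1.00    1.30    1.04    1.31    1.53
//
H SUYM030101
D Linker propensity index (synthetic stand-in values)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    1.02    1.04    0.94    0.94    0.74    1.26    1.08    0.93    1.07    0.94
    1.00    1.00    1.02    0.93    1.37    1.08    1.03    0.82    0.94    0.97
//
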