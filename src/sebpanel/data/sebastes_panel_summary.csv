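Locus,N,Na,Ho,He,F,Signif,MAF,A1,A2
SEB1,185,2,0.016,0.126,0.871,***,0.068,A,C
SEB2,186,2,0.005,0.057,0.906,***,0.030,C,T
SEB3,185,2,0.054,0.102,0.471,***,0.054,C,T
SEB4,185,2,0.005,0.058,0.906,***,0.030,A,C
SEB5,140,2,0.050,0.379,0.868,***,0.254,A,G
SEB6,118,2,0.085,0.387,0.781,***,0.263,A,G
SEB7,139,2,0.072,0.370,0.805,***,0.245,A,C
SEB8,175,2,0.320,0.496,0.355,***,0.457,C,T
SEB9,175,2,0.109,0.368,0.705,***,0.243,C,T
SEB10,141,2,0.035,0.415,0.915,***,0.294,A,G
SEB11,141,2,0.014,0.406,0.965,***,0.284,A,C
SEB12,168,2,0.363,0.500,0.273,***,0.485,C,T
SEB13,115,2,0.061,0.390,0.844,***,0.265,C,T
SEB14,138,2,0.101,0.405,0.750,***,0.283,G,T
SEB15,139,2,0.108,0.454,0.762,***,0.349,A,G
SEB16,134,2,0.119,0.400,0.701,***,0.276,A,T
SEB17,138,2,0.000,0.096,1.000,***,0.051,A,G
SEB18,129,2,0.217,0.467,0.535,***,0.372,A,G
SEB19,132,2,0.318,0.449,0.292,***,0.341,A,G
SEB20,137,2,0.161,0.441,0.636,***,0.328,A,G
SEB21,182,2,0.154,0.367,0.580,***,0.242,C,T
SEB22,132,2,0.356,0.499,0.286,**,0.473,A,G
SEB23,124,2,0.266,0.480,0.445,***,0.399,A,G
SEB24,142,2,0.035,0.499,0.929,***,0.475,A,G
SEB25,142,2,0.007,0.375,0.981,***,0.250,A,G
SEB26,140,2,0.121,0.399,0.695,***,0.275,C,T
SEB27,180,2,0.128,0.477,0.732,***,0.392,C,T
SEB28,175,2,0.189,0.499,0.622,***,0.477,G,T
SEB29,185,2,0.000,0.053,1.000,***,0.027,C,T
SEB30,188,2,0.005,0.057,0.906,***,0.029,C,T
SEB31,174,2,0.029,0.072,0.600,***,0.037,C,T
SEB32,184,2,0.043,0.294,0.852,***,0.179,G,T
SEB33,186,2,0.027,0.335,0.920,***,0.212,C,T
SEB34,183,2,0.098,0.500,0.803,***,0.486,A,G
SEB35,143,2,0.126,0.463,0.728,***,0.364,C,T
SEB36,184,2,0.033,0.352,0.907,***,0.228,C,T
SEB37,175,2,0.234,0.492,0.524,***,0.437,A,T
SEB38,143,2,0.126,0.500,0.748,***,0.497,A,G
SEB39,140,2,0.036,0.423,0.916,***,0.304,C,T
SEB40,132,2,0.083,0.461,0.819,***,0.360,A,G
SEB41,143,2,0.042,0.332,0.873,***,0.210,C,T
SEB42,135,2,0.289,0.498,0.420,***,0.470,G,T
SEB43,175,2,0.103,0.147,0.301,***,0.080,A,G
SEB44,181,2,0.044,0.084,0.477,***,0.044,A,G
SEB45,178,2,0.315,0.447,0.296,***,0.337,C,T
SEB46,179,2,0.168,0.264,0.365,***,0.156,C,T
SEB47,143,2,0.042,0.067,0.378,***,0.035,A,G
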