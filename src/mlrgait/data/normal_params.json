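{
  "format": "mlrgait-free-parameters",
  "length": 49,
  "index_map": {
    "u0": [
      0,
      1
    ],
    "w_feed": [
      1,
      17
    ],
    "w_cpg": [
      17,
      26
    ],
    "w_pos": [
      26,
      49
    ]
  },
  "values": [
    2.2937200809186464,
    8.676710691914034,
    5.048483548483018,
    7.446184741099172,
    9.8207649925972,
    0.0011577527940733476,
    6.442207806224625,
    0.7037741520553044,
    3.2374332863257687,
    2.7857763394763864,
    5.76960376726942,
    1.145305520585669,
    2.193775605715433,
    10.0,
    1.718199034089627,
    4.707676265991703,
    7.433804969129758,
    0.5,
    3.65825005388522,
    1.052149719390865,
    1.410275905680999,
    1.4062593857969254,
    1.3852845028047267,
    3.9539273675384177,
    0.15260903389071276,
    1.8903400085699573,
    19.51258863900911,
    28.16984519998583,
    40.0,
    37.30430937317311,
    26.54022011784466,
    0.0,
    22.34454386987779,
    38.93131725590459,
    15.79872569980251,
    27.23519834995692,
    33.230520913251105,
    6.544866585562438,
    5.630390992262691,
    6.395157469655559,
    32.80876421992543,
    31.38451118186497,
    0.0,
    40.0,
    39.82863975752164,
    4.09493730815614,
    16.17336513295988,
    39.026038972939475,
    2.12161594955688
  ],
  "meta": {
    "description": "GA-optimized normal-gait controller (staged optimization)",
    "fitness": 51.270534138291126,
    "distance_m": 20.04545705626735,
    "steps": 33,
    "speed_m_per_s": 1.3363638037511565,
    "cost_of_transport": 5.405315318347272
  }
}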