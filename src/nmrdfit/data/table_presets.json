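{
  "_comment": "Frozen transcription of the published fitted parameter sets for BSA-water mixtures (20%wt and 40%wt BSA). Units: C* in s^-2 (Hz^2), tau* in s, A in s^-1, N_H in m^-3, D_trans in m^2/s, d in m, a_Q in Hz, theta/phi in degrees. tau_d_consistent records whether the printed (tau_trans, D_trans) pair satisfies D = d^2/(2 tau).",
  "d": 2.7e-10,
  "lorentzian_sum": {
    "20wt": {
      "C_i": 7.84e6,
      "C_f": 2.16e7,
      "rows": {
        "268": {"tau_i": 1.97e-7, "tau_f": 2.28e-8, "A": 2.52},
        "273": {"tau_i": 1.65e-7, "tau_f": 1.91e-8, "A": 2.25},
        "278": {"tau_i": 1.27e-7, "tau_f": 1.39e-8, "A": 1.62},
        "298": {"tau_i": 8.33e-8, "tau_f": 9.62e-9, "A": 0.98}
      }
    },
    "40wt": {
      "C_s": 5.61e6,
      "C_i": 1.45e7,
      "C_f": 9.89e7,
      "rows": {
        "266": {"tau_s": 1.16e-6, "tau_i": 2.66e-7, "tau_f": 2.24e-8, "A": 4.68},
        "268": {"tau_s": 1.10e-6, "tau_i": 2.41e-7, "tau_f": 2.09e-8, "A": 4.50},
        "273": {"tau_s": 9.67e-7, "tau_i": 1.95e-7, "tau_f": 1.84e-8, "A": 3.91},
        "278": {"tau_s": 8.53e-7, "tau_i": 1.56e-7, "tau_f": 1.59e-8, "A": 3.40}
      }
    }
  },
  "ffhs_plus_lorentzian": {
    "tau_d_consistent": false,
    "20wt": {
      "C_DD": 7.29e6,
      "N_H": 1.52e27,
      "rows": {
        "268": {"tau_c": 1.85e-7, "D_trans": 2.08e-12, "A": 1.98, "tau_trans": 3.50e-8},
        "273": {"tau_c": 1.54e-7, "D_trans": 2.44e-12, "A": 1.79, "tau_trans": 2.98e-8},
        "278": {"tau_c": 1.18e-7, "D_trans": 3.28e-12, "A": 1.25, "tau_trans": 2.22e-8},
        "298": {"tau_c": 7.60e-8, "D_trans": 4.56e-12, "A": 0.69, "tau_trans": 1.60e-8}
      }
    },
    "40wt": {
      "C_DD": 7.69e6,
      "N_H": 2.84e27,
      "rows": {
        "266": {"tau_c": 9.08e-7, "D_trans": 5.56e-13, "A": 5.00, "tau_trans": 1.31e-7},
        "268": {"tau_c": 8.47e-7, "D_trans": 6.10e-13, "A": 4.84, "tau_trans": 1.20e-7},
        "273": {"tau_c": 7.32e-7, "D_trans": 7.23e-13, "A": 4.31, "tau_trans": 1.01e-7},
        "278": {"tau_c": 6.35e-7, "D_trans": 8.68e-13, "A": 3.82, "tau_trans": 8.40e-8}
      }
    }
  },
  "surface2d_long_res": {
    "tau_d_consistent": true,
    "20wt": {
      "C_DD": 9.81e6,
      "C_trans": 7.09e7,
      "rows": {
        "268": {"tau_c": 1.37e-7, "tau_trans": 7.26e-10, "A": 1.70, "D_trans": 5.02e-11},
        "273": {"tau_c": 1.14e-7, "tau_trans": 6.15e-10, "A": 1.55, "D_trans": 5.93e-11},
        "278": {"tau_c": 9.05e-8, "tau_trans": 4.05e-10, "A": 1.19, "D_trans": 9.00e-11},
        "298": {"tau_c": 5.99e-8, "tau_trans": 2.50e-10, "A": 0.77, "D_trans": 1.46e-10}
      }
    },
    "40wt": {
      "C_DD": 8.28e6,
      "C_trans": 7.09e7,
      "rows": {
        "266": {"tau_c": 6.92e-7, "tau_trans": 7.14e-9, "A": 4.32, "D_trans": 5.11e-12},
        "268": {"tau_c": 6.39e-7, "tau_trans": 6.64e-9, "A": 4.01, "D_trans": 5.49e-12},
        "273": {"tau_c": 5.42e-7, "tau_trans": 5.67e-9, "A": 3.50, "D_trans": 6.43e-12},
        "278": {"tau_c": 4.63e-7, "tau_trans": 4.79e-9, "A": 3.03, "D_trans": 7.61e-12}
      }
    }
  },
  "surface2d_res": {
    "tau_d_consistent": true,
    "20wt": {
      "C_DD": 4.31e7,
      "C_trans": 8.04e6,
      "rows": {
        "268": {"tau_c": 6.70e-9, "tau_trans": 5.17e-8, "tau_res": 4.81e-7, "A": 2.06, "D_trans": 7.05e-13},
        "273": {"tau_c": 5.46e-9, "tau_trans": 4.33e-8, "tau_res": 4.07e-7, "A": 1.90, "D_trans": 8.42e-13},
        "278": {"tau_c": 4.13e-9, "tau_trans": 3.28e-8, "tau_res": 3.12e-7, "A": 1.31, "D_trans": 1.11e-12},
        "298": {"tau_c": 2.78e-9, "tau_trans": 2.14e-8, "tau_res": 2.09e-7, "A": 0.80, "D_trans": 1.70e-12}
      }
    },
    "40wt": {
      "C_DD": 9.03e7,
      "C_trans": 1.07e7,
      "rows": {
        "266": {"tau_c": 2.38e-8, "tau_trans": 1.83e-7, "tau_res": 2.71e-6, "A": 5.06, "D_trans": 1.99e-13},
        "268": {"tau_c": 2.24e-8, "tau_trans": 1.65e-7, "tau_res": 2.66e-6, "A": 4.70, "D_trans": 2.21e-13},
        "273": {"tau_c": 1.91e-8, "tau_trans": 1.33e-7, "tau_res": 2.60e-6, "A": 4.20, "D_trans": 2.74e-13},
        "278": {"tau_c": 1.66e-8, "tau_trans": 1.07e-7, "tau_res": 2.60e-6, "A": 3.51, "D_trans": 3.41e-13}
      }
    }
  },
  "lorentzian_sum_plus_qre": {
    "40wt": {
      "rows": {
        "263": {
          "C_s": 4.92e6, "C_i": 1.40e8, "C_f": 5.62e8,
          "tau_s": 1.31e-6, "tau_i": 1.09e-7, "tau_f": 1.07e-8,
          "C_DD_HN": 2.27e7, "a_Q": 3.36e6, "eta": 0.42,
          "tau_Q": 1.03e-6, "theta": 55.4, "phi": 53.0,
          "A": 10.8
        }
      }
    }
  }
}
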