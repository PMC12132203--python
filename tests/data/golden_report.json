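{
  "pairwise": {},
  "provenance": {
    "config": {
      "cells_path": null,
      "growth_path": null,
      "log_scale": false,
      "n_bins": 9,
      "n_perm": 10000,
      "per_cell_correlation": false,
      "seed": 7,
      "sim": {
        "divisions_enabled": false,
        "ell_space": 0.0,
        "kappa_mt": 2.0,
        "mt_coupling": "independent",
        "n_cells": 60,
        "n_intervals": 3,
        "rho_time": 0.5,
        "seed": 7,
        "sigma_f": 0.1,
        "target_coeffs": [
          1.7,
          -1.2,
          0.9,
          -0.3
        ]
      },
      "tau_coherence": 0.6,
      "weighted_alignment": false
    },
    "seed": 7,
    "version": "0.1.0"
  },
  "replicates": {
    "sim": {
      "alignment": {
        "A_mg": -0.07862723320465707,
        "A_nn": 0.024082379843672685,
        "groups": {
          "mt_growth": {
            "difference": 0.07859004802375984,
            "overgrowing_mean": -0.03714915230322828,
            "p": 0.44155584441555845,
            "undergrowing_mean": -0.11573920032698812
          },
          "neighbor": {
            "difference": 0.02055938812956199,
            "overgrowing_mean": 0.03493316802316373,
            "p": 0.672032796720328,
            "undergrowing_mean": 0.014373779893601737
          }
        },
        "histogram_edges_deg": [
          0.0,
          10.0,
          20.0,
          30.0,
          40.0,
          50.0,
          60.0,
          70.0,
          80.0,
          90.0
        ],
        "histogram_mass": [
          7.388463862522363,
          7.179676157957619,
          7.5600858941451845,
          8.860810805615811,
          6.283912382731329,
          6.472401443483058,
          5.904064617768239,
          6.453148119283498,
          3.150324900762905
        ],
        "weighted": false
      },
      "heterogeneity": {
        "error": null,
        "excluded_cumulative": 0,
        "excluded_per_interval": {
          "0": 0,
          "1": 0,
          "2": 0
        },
        "n_cells": 60,
        "n_cumulative": 60,
        "patchiness": 0.15996854977522607,
        "r_bar": 0.600940213379485,
        "r_pairs": [
          0.5089272129140158,
          0.6929532138449541
        ],
        "undefined_pairs": []
      }
    }
  }
}
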