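{
  "schema_version": 1,
  "_comment": "Default (non-optimised) model parameters. Per-muscle values are representative approximations in the style of generic upper-limb musculoskeletal models (plausible magnitudes for an adult male arm); subject calibration adjusts them. Geometry curves are ascending-power cubics of the driving joint angle (rad): elbow muscles in elbow flexion theta2, shoulder muscles in shoulder elevation theta1. Moment arms: flexion-positive, extensors negative. Anthropometry: L_1 arm length (m), forearm_hand_length elbow-to-fingertip (m), L_2 elbow-to-handle lever (m), l_1 = L_1/2, l_2 = forearm_hand_length/2, masses for a 70 kg adult via Winter's fractions (arm 0.028, forearm+hand 0.022 of body mass).",
  "joints": {
    "elbow": {
      "joint": "elbow",
      "muscles": [
        {
          "name": "BB",
          "F_O": 624.3,
          "l_o": 0.116,
          "phi_o": 0.0,
          "A": -0.2,
          "sigma_A": 0.45,
          "coeff_l": [
            0.134,
            -0.02,
            0.001,
            0.0002
          ],
          "coeff_r": [
            0.015,
            0.035,
            -0.011,
            0.0004
          ]
        },
        {
          "name": "TB",
          "F_O": 798.5,
          "l_o": 0.134,
          "phi_o": 0.209,
          "A": -0.2,
          "sigma_A": 0.45,
          "coeff_l": [
            0.125,
            0.015,
            -0.002,
            0.0002
          ],
          "coeff_r": [
            -0.025,
            0.004,
            -0.002,
            0.0003
          ]
        }
      ]
    },
    "shoulder": {
      "joint": "shoulder",
      "muscles": [
        {
          "name": "BB",
          "F_O": 624.3,
          "l_o": 0.116,
          "phi_o": 0.0,
          "A": -0.2,
          "sigma_A": 0.45,
          "coeff_l": [
            0.125,
            -0.01,
            0.0008,
            -0.0002
          ],
          "coeff_r": [
            0.01,
            0.004,
            -0.002,
            0.0003
          ]
        },
        {
          "name": "TB",
          "F_O": 798.5,
          "l_o": 0.134,
          "phi_o": 0.209,
          "A": -0.2,
          "sigma_A": 0.45,
          "coeff_l": [
            0.13,
            0.008,
            -0.001,
            0.0002
          ],
          "coeff_r": [
            -0.012,
            0.002,
            -0.001,
            0.0002
          ]
        },
        {
          "name": "AD",
          "F_O": 1098.4,
          "l_o": 0.0976,
          "phi_o": 0.384,
          "A": -0.2,
          "sigma_A": 0.45,
          "coeff_l": [
            0.088,
            0.012,
            -0.003,
            0.0003
          ],
          "coeff_r": [
            0.019,
            0.01,
            -0.004,
            0.0005
          ]
        },
        {
          "name": "PD",
          "F_O": 944.7,
          "l_o": 0.1367,
          "phi_o": 0.314,
          "A": -0.2,
          "sigma_A": 0.45,
          "coeff_l": [
            0.13,
            0.01,
            -0.001,
            0.0002
          ],
          "coeff_r": [
            -0.021,
            -0.004,
            0.002,
            -0.0003
          ]
        }
      ]
    }
  },
  "anthropometry": {
    "M_a": 1.96,
    "M_fh": 1.54,
    "L_1": 0.31,
    "l_1": 0.155,
    "l_2": 0.24,
    "L_2": 0.33,
    "g": 9.81
  }
}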