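{
  "median": {
    "description": "Median-performing optimized bank from a 31-run search on the PH2 melanoma/nevus task",
    "filters": [
      {"m": 9, "sigma": 4.81270877, "theta": 3.13540763, "lambda": 7.47685794, "gamma": 0.31561081, "psi": 2.20899015},
      {"m": 8, "sigma": 1.96396977, "theta": 0.24860970, "lambda": 2.96959010, "gamma": 0.72105363, "psi": 4.60142864},
      {"m": 13, "sigma": 1.64780153, "theta": 1.61016196, "lambda": 2.83743557, "gamma": 0.66358951, "psi": 1.73766008},
      {"m": 15, "sigma": 3.39179532, "theta": 0.55921120, "lambda": 1.16027452, "gamma": 0.96851020, "psi": 0.19780057}
    ]
  },
  "best": {
    "description": "Best-fitness optimized bank from the same 31-run search",
    "filters": [
      {"m": 19, "sigma": 3.12069459, "theta": 1.51606866, "lambda": 3.89019095, "gamma": 0.65310207, "psi": 4.58528896},
      {"m": 7, "sigma": 3.02631751, "theta": 0.45433475, "lambda": 5.25153474, "gamma": 0.83115052, "psi": 2.04598812},
      {"m": 8, "sigma": 4.91978266, "theta": 1.01728566, "lambda": 1.73791384, "gamma": 0.62092611, "psi": 2.98742533},
      {"m": 8, "sigma": 2.76768679, "theta": 0.29284487, "lambda": 2.12407121, "gamma": 0.50966019, "psi": 4.89246233}
    ]
  },
  "worst": {
    "description": "Worst-fitness optimized bank from the same 31-run search",
    "filters": [
      {"m": 14, "sigma": 2.87441456, "theta": 0.64689645, "lambda": 7.50065226, "gamma": 0.48449909, "psi": 0.16186625},
      {"m": 9, "sigma": 4.60047050, "theta": 2.76179466, "lambda": 6.09504738, "gamma": 0.27625496, "psi": 1.01749004},
      {"m": 19, "sigma": 2.91841521, "theta": 1.58793182, "lambda": 5.60334183, "gamma": 0.17517662, "psi": 3.61273987},
      {"m": 10, "sigma": 1.54570447, "theta": 1.59859262, "lambda": 2.73917312, "gamma": 0.98337168, "psi": 1.01393177}
    ]
  }
}
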