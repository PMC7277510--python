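{
  "version": 1,
  "description": "Published per-step feature subsets retained by the Tukey HSD screening in the original study (verbatim transcription; sensor ids are this package's canonical tokens).",
  "steps": {
    "1": [
      ["NW_SnO2Au_350", "delta_r"],
      ["NW_SnO2Au_350", "area_to_extremum"],
      ["NW_SnO2Au_350", "total_area"],
      ["NW_SnO2Au_350", "transition_time"],
      ["NW_SnO2_350", "delta_r"],
      ["NW_SnO2_350", "area_to_extremum"],
      ["NW_SnO2_350", "total_area"],
      ["NW_SnO2_350", "transition_time"],
      ["NW_CuO_400", "delta_r"],
      ["NW_CuO_400", "area_to_extremum"],
      ["NW_CuO_400", "total_area"],
      ["NW_CuO_400", "transition_time"],
      ["TGS2611", "delta_r"],
      ["TGS2602", "delta_r"],
      ["TGS2602", "area_to_extremum"],
      ["TGS2602", "total_area"],
      ["TGS2602", "transition_time"],
      ["RGTO_SnO2_400", "delta_r"],
      ["RGTO_SnO2_400", "area_to_extremum"],
      ["RGTO_SnO2_400", "total_area"],
      ["RGTO_SnO2_400", "transition_time"],
      ["RGTO_SnO2Au_400", "deriv_extremum"]
    ],
    "2": [
      ["RGTO_SnO2_300", "deriv_extremum"],
      ["RGTO_SnO2_300", "area_to_extremum"],
      ["NW_SnO2Au_350", "delta_r"],
      ["NW_SnO2Au_350", "deriv_extremum"],
      ["NW_SnO2Au_350", "area_to_extremum"],
      ["NW_SnO2Au_350", "total_area"],
      ["NW_SnO2_350", "area_to_extremum"],
      ["NW_CuO_400", "deriv_extremum"],
      ["TGS2611", "delta_r"],
      ["TGS2611", "area_to_extremum"],
      ["TGS2602", "area_to_extremum"],
      ["TGS2602", "transition_time"],
      ["RGTO_SnO2_400", "transition_time"],
      ["RGTO_SnO2Au_400", "deriv_extremum"]
    ],
    "3": [
      ["RGTO_SnO2_300", "deriv_extremum"],
      ["NW_SnO2Au_350", "delta_r"],
      ["NW_SnO2Au_350", "deriv_extremum"],
      ["NW_SnO2Au_350", "area_to_extremum"],
      ["NW_SnO2_350", "delta_r"],
      ["NW_SnO2_350", "area_to_extremum"],
      ["NW_SnO2_350", "transition_time"],
      ["NW_CuO_400", "delta_r"],
      ["NW_CuO_400", "deriv_extremum"],
      ["NW_CuO_400", "area_to_extremum"],
      ["NW_CuO_400", "total_area"],
      ["TGS2611", "total_area"],
      ["TGS2611", "transition_time"],
      ["TGS2602", "delta_r"],
      ["RGTO_SnO2_400", "delta_r"],
      ["RGTO_SnO2_400", "area_to_extremum"],
      ["RGTO_SnO2_400", "total_area"],
      ["RGTO_SnO2Au_400", "delta_r"],
      ["RGTO_SnO2Au_400", "area_to_extremum"],
      ["RGTO_SnO2Au_400", "total_area"]
    ]
  }
}
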