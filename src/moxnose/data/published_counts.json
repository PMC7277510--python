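{
  "version": 1,
  "description": "Published replica counts for the grated Parmigiano Reggiano study design: seasoning x rind working process x rind class, plus zero-rind replicas that carry no working process.",
  "cells": {
    "M12": {
      "WR": {"LE18": 23, "PCT19_26": 21, "GT26": 61},
      "SR": {"LE18": 26, "PCT19_26": 24, "GT26": 42}
    },
    "M24": {
      "WR": {"LE18": 36, "PCT19_26": 26, "GT26": 41},
      "SR": {"LE18": 38, "PCT19_26": 23, "GT26": 65}
    }
  },
  "zero_rind": {"M12": 14, "M24": 12}
}
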