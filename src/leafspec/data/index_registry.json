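{
  "version": "1.0",
  "description": "Published hyperspectral vegetation indices compared against Vcmax and Jmax. Formulas are over rho(lambda) = raw reflectance at the 1-nm grid point. Entries with extra=true are supplementary variants outside the 19-index comparison suite.",
  "indices": [
    {
      "name": "SR1",
      "formula": "r750 / r700",
      "wavelengths": [
        750,
        700
      ],
      "group": "chlorophyll",
      "reference": "Gitelson & Merzlyak 1997"
    },
    {
      "name": "DoubleDifference",
      "formula": "(r749 - r720) - (r701 - r672)",
      "wavelengths": [
        749,
        720,
        701,
        672
      ],
      "group": "chlorophyll",
      "reference": "le Maire et al. 2004"
    },
    {
      "name": "Vogelmann1",
      "formula": "r740 / r720",
      "wavelengths": [
        740,
        720
      ],
      "group": "chlorophyll",
      "reference": "Vogelmann et al. 1993"
    },
    {
      "name": "mSR705",
      "formula": "(r750 - r445) / (r705 - r445)",
      "wavelengths": [
        750,
        705,
        445
      ],
      "group": "chlorophyll",
      "reference": "Sims & Gamon 2002"
    },
    {
      "name": "SRCarter",
      "formula": "r760 / r695",
      "wavelengths": [
        760,
        695
      ],
      "group": "stress",
      "reference": "Carter 1994"
    },
    {
      "name": "Maccioni",
      "formula": "(r780 - r710) / (r780 - r680)",
      "wavelengths": [
        780,
        710,
        680
      ],
      "group": "chlorophyll",
      "reference": "Maccioni et al. 2001"
    },
    {
      "name": "SR3",
      "formula": "r750 / r550",
      "wavelengths": [
        750,
        550
      ],
      "group": "chlorophyll",
      "reference": "Gitelson & Merzlyak 1997"
    },
    {
      "name": "Gitelson",
      "formula": "1 / r700",
      "wavelengths": [
        700
      ],
      "group": "chlorophyll",
      "reference": "Gitelson et al. 1999"
    },
    {
      "name": "NDVI_MODIS",
      "formula": "(NIR_band - red_band) / (NIR_band + red_band)",
      "wavelengths": [],
      "band_ranges": {
        "red": [
          620,
          670
        ],
        "nir": [
          841,
          876
        ]
      },
      "group": "greenness",
      "reference": "broadband approximation"
    },
    {
      "name": "Datt4",
      "formula": "r672 / (r550 * r708)",
      "wavelengths": [
        672,
        550,
        708
      ],
      "group": "chlorophyll",
      "reference": "Datt 1998"
    },
    {
      "name": "SR4",
      "formula": "r700 / r670",
      "wavelengths": [
        700,
        670
      ],
      "group": "chlorophyll",
      "reference": "McMurtrey et al. 1994"
    },
    {
      "name": "SR2",
      "formula": "r752 / r690",
      "wavelengths": [
        752,
        690
      ],
      "group": "chlorophyll",
      "reference": "Gitelson & Merzlyak 1997"
    },
    {
      "name": "NDVI",
      "formula": "(r860 - r690) / (r860 + r690)",
      "wavelengths": [
        860,
        690
      ],
      "group": "greenness",
      "reference": "Stimson et al. 2005"
    },
    {
      "name": "Vogelmann2",
      "formula": "(r734 - r747) - (r715 + r726)",
      "wavelengths": [
        734,
        747,
        715,
        726
      ],
      "group": "chlorophyll",
      "reference": "Vogelmann et al. 1993",
      "note": "variant form kept deliberately: a double difference, where the 1993 original uses the ratio (r734-r747)/(r715+r726)"
    },
    {
      "name": "mNDVI",
      "formula": "(r800 - r680) / (r800 + r680 - 2*r445)",
      "wavelengths": [
        800,
        680,
        445
      ],
      "group": "chlorophyll",
      "reference": "Sims & Gamon 2002"
    },
    {
      "name": "NDWI",
      "formula": "(r860 - r1240) / (r860 + r1240)",
      "wavelengths": [
        860,
        1240
      ],
      "group": "water",
      "reference": "Gao 1996"
    },
    {
      "name": "SIPI",
      "formula": "r800 - r445",
      "wavelengths": [
        800,
        445
      ],
      "group": "carotenoid",
      "reference": "Penuelas et al. 1995",
      "note": "variant form kept deliberately: truncated two-band difference; the conventional full form is available as SIPI_full"
    },
    {
      "name": "PRI",
      "formula": "(r531 - r570) / (r531 + r570)",
      "wavelengths": [
        531,
        570
      ],
      "group": "xanthophyll",
      "reference": "Gamon et al. 1997"
    },
    {
      "name": "mSRCHL",
      "formula": "(r800 - r445) / (r680 - r445)",
      "wavelengths": [
        800,
        445,
        680
      ],
      "group": "chlorophyll",
      "reference": "Sims & Gamon 2002"
    },
    {
      "name": "SIPI_full",
      "formula": "(r800 - r445) / (r800 - r680)",
      "wavelengths": [
        800,
        445,
        680
      ],
      "group": "carotenoid",
      "reference": "Penuelas et al. 1995",
      "extra": true
    }
  ]
}
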