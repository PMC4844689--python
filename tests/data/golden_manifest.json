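{
  "outputs": {
    "activity.tsv": "48483f6b01970eaf19da504ba0b86dc6f86bb5dd771cca61c67de82c4d6fe6d3",
    "area_tree.nwk": "e2a2fdfd7444d1a3f5763ca88f014bb424660cdcbbdbd30ab8410a9dc8375fa8",
    "areas.tsv": "e7a2f274700ab638d26a1c0b20cde05c440f48a7315bcc57d1693000dda782fd",
    "host_tree.nwk": "5d169c97c5e0166d1978c1f1d5736b49180f0f54ba61803e81371e42136dc3a8",
    "newwave/consensus.fasta": "15d232f9cc49dcc3ab61198243a2dc04320e01bbc71091b3db44b3a0ddd51830",
    "newwave/copies.fasta": "1f02fc0ea446053655bfee3fb0727c5734507d4f8f8b7c1232a88c44482eeadc",
    "newwave/divergence.tsv": "4f9318d5b014964c7979a4fea7689f481a06c5d46139c79c5c1d672d84919dff",
    "newwave/landscape.tsv": "4e11145bc5891e4e32447614d9130ec1b69acdcc85109269bc38d70401d9bc95",
    "newwave/master.fasta": "0d954dd3c87b2e8086008fb510c85308fb5f0527502f28ca9f150bbc73a3795d",
    "newwave/support.tsv": "0d437aab89226222d3616e474070eb49c8d35e9415905bbcc5ce1b469ed20ef9",
    "newwave2/consensus.fasta": "5b44f3cca2052801dfd4cc11505ef0e9bcdfa215f43143d157ae21e1daddacf3",
    "newwave2/copies.fasta": "46f07739cd839bd25d38e740eaa492d97f41d40b063a2e1c089a755147cc2b7c",
    "newwave2/divergence.tsv": "33c6f82c6912d92f696d4fb3bcfeeb0eae0bff423f63fffb6466f4f74c3f4217",
    "newwave2/landscape.tsv": "47e31fca681679e3a21f6c2cf97ca40b9300b1798fef100ba48b2de85a8ab1a9",
    "newwave2/master.fasta": "02a514dbbbf1c32cf3098baa153255e55fc33e5ca2317f72a1fbc52e375bddd5",
    "newwave2/support.tsv": "fc49bda5f4eac55f48d60798d2a5f09d55b386e998b8da3befce6b71d0d9f079",
    "oldwave/consensus.fasta": "f0ec80f25cebd2a5ed8ff6c93ceac32a2a34567b804d0ad9e93975818cd911a3",
    "oldwave/copies.fasta": "db13c8b871eeef29b120496f4d2bbf492a0c1f75fb487efc91b9ce945630d4ff",
    "oldwave/divergence.tsv": "da5475e3c5b78f71f9789aaac7f12fe2e73e26821bfbb778ce9078b7e351451e",
    "oldwave/landscape.tsv": "27aeeabccc325f1e1fd6d17cfbcefe29821c14699e41b861753b2347a9383169",
    "oldwave/master.fasta": "1f73863258c4823f2a43895d42ba854a3e581e1d6796df5e0238f5d90701cf33",
    "oldwave/support.tsv": "57631a3eb72c81342863e1b57b8fb29e00dd9a9338cad9764db13038ec5e6754",
    "oldwave2/consensus.fasta": "2b8720f592ab0e2d7ff87e926260c6a1df21ae27aad0d49c2ccf705ba404b3a3",
    "oldwave2/copies.fasta": "ed1e17a243cdb453a57b932bec632093f4e3d2c0eea0f2613607c5d77185fb79",
    "oldwave2/divergence.tsv": "9a92b55f1c7982ed8a66aa2f63a42962d222d0d83d75807c653b7bb30b4b4f65",
    "oldwave2/landscape.tsv": "cbab97a85ff5d8d375e72df087b1064c18a8cb11e36aad70e218b70058535279",
    "oldwave2/master.fasta": "08f579cc78de4c1826b623b94ee7106cb31f54e7dd78d1cbde050fb4b2876cbd",
    "oldwave2/support.tsv": "fbbfbd5bfa6e1bde97c24debaf92730a398a8479810be48df964464fa0c34a14",
    "reconciliation.tsv": "884d2566905f2b722a36830c0c9ee196f83b3369f255c471c5b8550676b7a167",
    "te_tree.nwk": "2fcd8cf578a830874b36ef5e6c2c670be728902f7456d9363c04adcc3ca5fa01",
    "waves.tsv": "28acaf09bc8557ad36c143b6f62bdbc3ecfca4b7b4a51d574afae0d00d7fc0a4"
  },
  "package": "horizonte",
  "results": {
    "diva_cost": 2,
    "invasion_min_myr": {
      "newwave": 13.5189,
      "newwave2": 12.286,
      "oldwave": 17.0081,
      "oldwave2": 18.5606
    },
    "transfer_count": 3,
    "wave_pvalue": 0.04290114
  },
  "seed": 20160421,
  "version": "0.1.0"
}
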