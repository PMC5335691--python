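((NC_017600.1,(NC_030280.1,((NC_029457.1,(NC_026834.1,NC_030277.1)),(NC_002184.1,(NC_007010.1,((NC_009679.1,(NC_026884.1,NC_026885.1)),(NC_012738.1,NC_009626.1))))))),((((NC_018778.1,NC_020313.1),(NC_021971.1,(NC_020311.1,(NC_027116.1,NC_020310.1)))),((NC_024751.1,KU726823.1),(NC_008413.1,(NC_023823.1,NC_027603.1)))),(((NC_014883.1,KP276147.1),((KM978918.1,(NC_012217.1,(NC_015073.1,NC_006880.1))),(NC_012566.1,(NC_029240.1,NC_027601.1)))),((NC_019608.1,(NC_019606.1,(NC_019607.1,(NC_020023.1,NC_025943.1)))),(NC_019609.1,(NC_024651.1,(NC_020025.1,((NC_020351.1,NC_019610.1),((KU350630.1,KU362925.1),KM501040.2)))))))));
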