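# 372 human miRNA assay names for the default 384-well panel layout
hsa-mir-512
hsa-mir-509
hsa-mir-99a
hsa-mir-100
hsa-mir-182
hsa-mir-199b
hsa-mir-214
hsa-mir-200b
hsa-mir-205
hsa-mir-409
hsa-mir-29c
hsa-mir-30c
hsa-mir-20a
hsa-let-7d
hsa-mir-34a
hsa-mir-210
hsa-mir-195
hsa-mir-15b
hsa-let-7g
hsa-mir-9
hsa-mir-331
hsa-mir-186
hsa-mir-449c
hsa-mir-495
hsa-mir-449b
hsa-mir-200c
hsa-mir-449a
hsa-mir-486
hsa-mir-429
hsa-mir-34c
hsa-mir-34b
hsa-mir-154
hsa-let-7a
hsa-let-7b
hsa-let-7c
hsa-let-7e
hsa-let-7f
hsa-let-7i
hsa-mir-1
hsa-mir-7
hsa-mir-10a
hsa-mir-10b
hsa-mir-15a
hsa-mir-16
hsa-mir-17
hsa-mir-18a
hsa-mir-19a
hsa-mir-19b
hsa-mir-21
hsa-mir-22
hsa-mir-23a
hsa-mir-23b
hsa-mir-24
hsa-mir-25
hsa-mir-26a
hsa-mir-26b
hsa-mir-27a
hsa-mir-27b
hsa-mir-28
hsa-mir-29a
hsa-mir-29b
hsa-mir-30a
hsa-mir-30b
hsa-mir-30d
hsa-mir-30e
hsa-mir-31
hsa-mir-32
hsa-mir-33a
hsa-mir-92a
hsa-mir-93
hsa-mir-95
hsa-mir-96
hsa-mir-98
hsa-mir-99b
hsa-mir-101
hsa-mir-103
hsa-mir-105
hsa-mir-106a
hsa-mir-106b
hsa-mir-107
hsa-mir-122
hsa-mir-124
hsa-mir-125a
hsa-mir-125b
hsa-mir-126
hsa-mir-127
hsa-mir-128
hsa-mir-129
hsa-mir-130a
hsa-mir-130b
hsa-mir-132
hsa-mir-133a
hsa-mir-133b
hsa-mir-134
hsa-mir-135a
hsa-mir-135b
hsa-mir-136
hsa-mir-137
hsa-mir-138
hsa-mir-139
hsa-mir-140
hsa-mir-141
hsa-mir-142
hsa-mir-143
hsa-mir-144
hsa-mir-145
hsa-mir-146a
hsa-mir-146b
hsa-mir-147
hsa-mir-148a
hsa-mir-148b
hsa-mir-149
hsa-mir-150
hsa-mir-151
hsa-mir-152
hsa-mir-153
hsa-mir-155
hsa-mir-181a
hsa-mir-181b
hsa-mir-181c
hsa-mir-181d
hsa-mir-183
hsa-mir-184
hsa-mir-185
hsa-mir-187
hsa-mir-188
hsa-mir-190
hsa-mir-191
hsa-mir-192
hsa-mir-193a
hsa-mir-193b
hsa-mir-194
hsa-mir-196a
hsa-mir-196b
hsa-mir-197
hsa-mir-198
hsa-mir-199a
hsa-mir-200a
hsa-mir-202
hsa-mir-203
hsa-mir-204
hsa-mir-206
hsa-mir-208a
hsa-mir-211
hsa-mir-212
hsa-mir-215
hsa-mir-216a
hsa-mir-217
hsa-mir-218
hsa-mir-219
hsa-mir-221
hsa-mir-222
hsa-mir-223
hsa-mir-224
hsa-mir-296
hsa-mir-298
hsa-mir-299
hsa-mir-301a
hsa-mir-301b
hsa-mir-302a
hsa-mir-302b
hsa-mir-302c
hsa-mir-302d
hsa-mir-320a
hsa-mir-323
hsa-mir-324
hsa-mir-325
hsa-mir-326
hsa-mir-328
hsa-mir-329
hsa-mir-330
hsa-mir-335
hsa-mir-337
hsa-mir-338
hsa-mir-339
hsa-mir-340
hsa-mir-342
hsa-mir-345
hsa-mir-346
hsa-mir-361
hsa-mir-362
hsa-mir-363
hsa-mir-365
hsa-mir-367
hsa-mir-369
hsa-mir-370
hsa-mir-371
hsa-mir-372
hsa-mir-373
hsa-mir-374a
hsa-mir-374b
hsa-mir-375
hsa-mir-376a
hsa-mir-376b
hsa-mir-376c
hsa-mir-377
hsa-mir-378
hsa-mir-379
hsa-mir-380
hsa-mir-381
hsa-mir-382
hsa-mir-383
hsa-mir-384
hsa-mir-410
hsa-mir-411
hsa-mir-412
hsa-mir-421
hsa-mir-422a
hsa-mir-423
hsa-mir-424
hsa-mir-425
hsa-mir-431
hsa-mir-432
hsa-mir-433
hsa-mir-448
hsa-mir-450a
hsa-mir-450b
hsa-mir-451
hsa-mir-452
hsa-mir-453
hsa-mir-454
hsa-mir-455
hsa-mir-483
hsa-mir-484
hsa-mir-485
hsa-mir-487a
hsa-mir-487b
hsa-mir-488
hsa-mir-489
hsa-mir-490
hsa-mir-491
hsa-mir-492
hsa-mir-493
hsa-mir-494
hsa-mir-496
hsa-mir-497
hsa-mir-498
hsa-mir-499
hsa-mir-500
hsa-mir-501
hsa-mir-502
hsa-mir-503
hsa-mir-504
hsa-mir-505
hsa-mir-506
hsa-mir-507
hsa-mir-508
hsa-mir-510
hsa-mir-511
hsa-mir-513a
hsa-mir-514
hsa-mir-515
hsa-mir-516a
hsa-mir-516b
hsa-mir-517a
hsa-mir-517b
hsa-mir-517c
hsa-mir-518a
hsa-mir-518b
hsa-mir-518c
hsa-mir-518d
hsa-mir-518e
hsa-mir-518f
hsa-mir-519a
hsa-mir-519b
hsa-mir-519c
hsa-mir-519d
hsa-mir-519e
hsa-mir-520a
hsa-mir-520b
hsa-mir-520c
hsa-mir-520d
hsa-mir-520e
hsa-mir-520f
hsa-mir-520g
hsa-mir-520h
hsa-mir-521
hsa-mir-522
hsa-mir-523
hsa-mir-524
hsa-mir-525
hsa-mir-526a
hsa-mir-526b
hsa-mir-527
hsa-mir-532
hsa-mir-539
hsa-mir-542
hsa-mir-544
hsa-mir-545
hsa-mir-548a
hsa-mir-548b
hsa-mir-548c
hsa-mir-548d
hsa-mir-550
hsa-mir-551a
hsa-mir-551b
hsa-mir-552
hsa-mir-553
hsa-mir-554
hsa-mir-555
hsa-mir-556
hsa-mir-557
hsa-mir-558
hsa-mir-559
hsa-mir-561
hsa-mir-562
hsa-mir-563
hsa-mir-564
hsa-mir-566
hsa-mir-567
hsa-mir-568
hsa-mir-569
hsa-mir-570
hsa-mir-571
hsa-mir-572
hsa-mir-573
hsa-mir-574
hsa-mir-575
hsa-mir-576
hsa-mir-577
hsa-mir-578
hsa-mir-579
hsa-mir-580
hsa-mir-581
hsa-mir-582
hsa-mir-583
hsa-mir-584
hsa-mir-585
hsa-mir-586
hsa-mir-587
hsa-mir-588
hsa-mir-589
hsa-mir-590
hsa-mir-591
hsa-mir-592
hsa-mir-593
hsa-mir-595
hsa-mir-596
hsa-mir-597
hsa-mir-598
hsa-mir-599
hsa-mir-600
hsa-mir-601
hsa-mir-602
hsa-mir-603
hsa-mir-604
hsa-mir-605
hsa-mir-606
hsa-mir-607
hsa-mir-608
hsa-mir-609
hsa-mir-610
hsa-mir-611
hsa-mir-612
hsa-mir-613
hsa-mir-614
hsa-mir-615
hsa-mir-616
hsa-mir-617
hsa-mir-618
hsa-mir-619
hsa-mir-620
hsa-mir-621
hsa-mir-622
hsa-mir-623
hsa-mir-624
hsa-mir-625
hsa-mir-626
hsa-mir-627
hsa-mir-628
hsa-mir-629
hsa-mir-630
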